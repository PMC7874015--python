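"""File-based pipeline: simulate -> qc -> dedupe -> relate -> pedigree -> report.

Stages communicate via files under one output directory so any stage can be
rerun or audited in isolation; a manifest records what each stage wrote.
Every number in the final report is recomputable from the stage TSVs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import identity, io, pedigree, qc, simulate
from .panel import GenotypePanel

log = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "dedupe", "relate", "pedigree", "report"]


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, with field-standard defaults.

    Thresholds: identity mismatch 0.12%, PO at k0 < 0.03, FS at k2 > 0.3,
    LD pruning at r^2 > 0.8, trio error rate 0.2%, SD rule z >= 4 with
    carrier excess >= 0.15 over >= 100 informative markers, kinship floor
    0.13 for unclassified close relatives.
    """

    out_dir: str = "grapekin_run"
    seed: int = 0
    # input: either a simulation or an existing panel file
    input_path: str | None = None
    input_format: str = "vcf"
    sim_n_markers: int = 6800
    sim_error_rate: float = 1e-4
    sim_missing_rate: float = 0.005
    # thresholds
    marker_max_missing: float = 0.01
    marker_min_maf: float = 0.05
    identity_threshold_pct: float = 0.12
    identity_min_compared: int = 500
    individual_preset: str = "parentage"
    ld_r2_max: float = 0.8
    ld_window: int = 50
    ld_step: int = 5
    k0_max: float = 0.03
    trio_max_error_rate: float = 0.002
    k2_min: float = 0.3
    sd_z_min: float = 4.0
    sd_min_excess: float = 0.15
    sd_min_informative: int = 100
    sd_both_hom_classes: bool = True
    sd_m_min: int = 2
    phi_min: float = 0.13

    def validate(self) -> None:
        for name, lo, hi in [
            ("marker_max_missing", 0, 1), ("marker_min_maf", 0, 0.5),
            ("sim_error_rate", 0, 1), ("sim_missing_rate", 0, 1),
            ("k0_max", 0, 1), ("trio_max_error_rate", 0, 1), ("k2_min", 0, 1),
            ("phi_min", 0, 0.5),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.identity_threshold_pct <= 0:
            raise ValueError("identity_threshold_pct must be > 0")
        if self.individual_preset not in qc.INDIVIDUAL_PRESETS:
            raise ValueError(f"unknown preset {self.individual_preset!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _update_manifest(out: Path, stage: str, files: list[str]) -> None:
    mpath = out / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {"stages": {}}
    manifest["stages"][stage] = sorted(files)
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# -- stages -------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> None:
    """Write a standard-scenario panel and its truth tables."""
    out = _out(cfg)
    sc = simulate.standard_scenario(
        cfg.seed, cfg.sim_n_markers, cfg.sim_error_rate, cfg.sim_missing_rate
    )
    io.write_dosage_table(sc.panel, out / "panel.tsv")
    sc.truth.to_tsv(out / "truth_parents.tsv", out / "truth_clones.tsv")
    sc.config.to_yaml(out / "sim_config.yaml")
    _update_manifest(out, "simulate", [
        "panel.tsv", "panel.tsv.markers.tsv", "truth_parents.tsv",
        "truth_clones.tsv", "sim_config.yaml",
    ])


def _load_input(cfg: PipelineConfig, out: Path) -> GenotypePanel:
    if (out / "panel.tsv").exists():
        return io.read_dosage_table(out / "panel.tsv")
    if cfg.input_path is None:
        raise FileNotFoundError("no simulated panel in out_dir and no input_path set")
    return io.read_panel(cfg.input_path, cfg.input_format)


def stage_qc(cfg: PipelineConfig) -> None:
    """Marker QC on the raw panel; per-individual QC report (qc preset)."""
    out = _out(cfg)
    panel = _load_input(cfg, out)
    filtered, marker_report = qc.filter_markers(
        panel, cfg.marker_max_missing, cfg.marker_min_maf
    )
    kept, indiv_report = qc.filter_individuals(filtered, preset="qc")
    qc.marker_qc(filtered).to_csv(out / "marker_qc.tsv", sep="\t")
    qc.individual_qc(kept).to_csv(out / "individual_qc.tsv", sep="\t")
    marker_report.to_csv(out / "removed_markers.tsv", sep="\t")
    indiv_report.to_csv(out / "removed_individuals.tsv", sep="\t")
    io.write_dosage_table(kept, out / "panel_qc.tsv")
    _update_manifest(out, "qc", [
        "panel_qc.tsv", "panel_qc.tsv.markers.tsv", "marker_qc.tsv",
        "individual_qc.tsv", "removed_markers.tsv", "removed_individuals.tsv",
    ])


def stage_dedupe(cfg: PipelineConfig) -> None:
    """Pairwise mismatch, identity clustering, one representative kept."""
    out = _out(cfg)
    panel = io.read_dosage_table(out / "panel_qc.tsv")
    mm = identity.pairwise_mismatch(panel, cfg.identity_min_compared)
    clusters = identity.cluster_identicals(mm, cfg.identity_threshold_pct, panel)
    deduped, mapping = identity.dedupe(panel, clusters)
    mm.to_frame().to_csv(out / "mismatch.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"cluster": i, "representative": c.representative,
             "n_members": len(c.members), "members": ";".join(c.members),
             "max_internal_mismatch_pct": c.max_internal_mismatch}
            for i, c in enumerate(clusters)
        ]
    ).to_csv(out / "clusters.tsv", sep="\t", index=False)
    mapping.to_csv(out / "dedupe_mapping.tsv", sep="\t", index=False)
    io.write_dosage_table(deduped, out / "panel_dedup.tsv")
    _update_manifest(out, "dedupe", [
        "mismatch.tsv", "clusters.tsv", "dedupe_mapping.tsv",
        "panel_dedup.tsv", "panel_dedup.tsv.markers.tsv",
    ])


def stage_relate(cfg: PipelineConfig) -> None:
    """Parentage-grade QC, LD pruning, all-pairs IBD + duo errors."""
    out = _out(cfg)
    panel = io.read_dosage_table(out / "panel_dedup.tsv")
    kept, report = qc.filter_individuals(panel, preset=cfg.individual_preset)
    pruned, dropped = qc.ld_prune(kept, cfg.ld_r2_max, cfg.ld_window, cfg.ld_step)
    ibd = pedigree.find_po_duos(
        kept, cfg.k0_max, pruned_panel=pruned
    )[1]  # the all-pairs table; edges are re-derived in stage_pedigree
    report.to_csv(out / "removed_individuals_parentage.tsv", sep="\t")
    pd.Series(dropped, name="marker_id").to_csv(
        out / "ld_pruned_markers.tsv", sep="\t", index=False
    )
    ibd.to_csv(out / "ibd_pairs.tsv", sep="\t", index=False, float_format="%.17g")
    io.write_dosage_table(kept, out / "panel_parentage.tsv")
    _update_manifest(out, "relate", [
        "ibd_pairs.tsv", "ld_pruned_markers.tsv",
        "removed_individuals_parentage.tsv",
        "panel_parentage.tsv", "panel_parentage.tsv.markers.tsv",
    ])


def stage_pedigree(cfg: PipelineConfig) -> None:
    """Duos, trios, FS, SD scans, direction inference, network export."""
    out = _out(cfg)
    panel = io.read_dosage_table(out / "panel_parentage.tsv")
    ibd = pd.read_csv(out / "ibd_pairs.tsv", sep="\t", float_precision="round_trip")
    duos = [
        pedigree.RelationshipEdge(
            r.id1, r.id2, "PO", k0=r.k0, k1=r.k1, k2=r.k2, kinship=r.kinship,
            duo_errors=int(r.duo_errors),
        )
        for r in ibd.itertuples()
        if r.k0 < cfg.k0_max
    ]
    trios, tested = pedigree.find_trios(panel, duos, cfg.trio_max_error_rate)
    fs_edges = pedigree.find_fullsibs(ibd, duos, cfg.k2_min)
    sd_results, sd_counts = pedigree.sd_scan_duos(
        panel, duos, trios, fs_edges,
        min_informative=cfg.sd_min_informative, z_min=cfg.sd_z_min,
        min_excess=cfg.sd_min_excess, both_hom_classes=cfg.sd_both_hom_classes,
    )
    graph = pedigree.infer_directions(duos, trios, fs_edges, sd_counts, cfg.sd_m_min)

    pd.DataFrame(
        [
            {"offspring": t.offspring, "parent1": t.parent1, "parent2": t.parent2,
             "errors": t.mendelian_errors, "error_rate": t.error_rate,
             "n_valid": t.n_valid,
             "accepted": t.error_rate <= cfg.trio_max_error_rate}
            for t in tested
        ],
        columns=["offspring", "parent1", "parent2", "errors", "error_rate",
                 "n_valid", "accepted"],
    ).to_csv(out / "trios.tsv", sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        [
            {"parent_assumed": r.parent_assumed, "offspring": r.offspring,
             "candidate": r.candidate, "n_informative": r.n_informative,
             "f_obs": r.f_obs, "f_exp": r.f_exp, "z": r.z, "accepted": r.accepted}
            for r in sd_results
        ],
        columns=["parent_assumed", "offspring", "candidate", "n_informative",
                 "f_obs", "f_exp", "z", "accepted"],
    ).to_csv(out / "sd_scan.tsv", sep="\t", index=False, float_format="%.17g")
    pedigree.export_network(graph, out / "edges.tsv", "edge_tsv")
    pedigree.export_network(graph, out / "network.graphml", "graphml")
    pedigree.export_network(graph, out / "network.dot", "dot")
    _update_manifest(out, "pedigree", [
        "trios.tsv", "sd_scan.tsv", "edges.tsv", "network.graphml", "network.dot",
    ])


def stage_report(cfg: PipelineConfig) -> None:
    """Machine-readable summary + human-readable markdown, from stage TSVs."""
    out = _out(cfg)
    raw = io.read_dosage_table(out / "panel.tsv") if (out / "panel.tsv").exists() else None
    panel_qc_ = io.read_dosage_table(out / "panel_qc.tsv")
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t")
    edges = pd.read_csv(out / "edges.tsv", sep="\t")
    trios = pd.read_csv(out / "trios.tsv", sep="\t")
    sd = pd.read_csv(out / "sd_scan.tsv", sep="\t")
    removed_markers = pd.read_csv(out / "removed_markers.tsv", sep="\t", index_col=0)

    n_indiv = panel_qc_.n_samples
    n_unique = int(len(clusters))
    po = edges[edges["relation"] == "PO"]
    directions = po["direction"].fillna("")
    summary = {
        "n_individuals_input": int(raw.n_samples) if raw is not None else n_indiv,
        "n_markers_input": int(raw.n_markers) if raw is not None else None,
        "n_markers_post_qc": int(panel_qc_.n_markers),
        "n_markers_removed": int(len(removed_markers)),
        "n_individuals_post_qc": n_indiv,
        "n_unique_genotypes": n_unique,
        "duplicate_fraction": 1.0 - n_unique / n_indiv if n_indiv else float("nan"),
        "n_po_duos": int(len(po)),
        "n_trios_accepted": int(trios["accepted"].sum()) if len(trios) else 0,
        "n_trios_tested": int(len(trios)),
        "n_fs": int((edges["relation"] == "FS").sum()),
        "n_sd_accepted": int(sd["accepted"].sum()) if len(sd) else 0,
        "n_po_directed": int((directions != "").sum()),
        "n_po_undirected": int((directions == "").sum()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    lines = [
        "# Parentage pipeline report", "",
        "## QC attrition",
        f"- markers: {summary['n_markers_input']} -> {summary['n_markers_post_qc']} "
        f"({summary['n_markers_removed']} removed)",
        f"- individuals retained: {summary['n_individuals_post_qc']}",
        "",
        "## Duplicates",
        f"- unique genotypes: {summary['n_unique_genotypes']}",
        f"- duplicate fraction: {summary['duplicate_fraction']:.3f}",
        "",
        "## Relationships",
        f"- PO duos: {summary['n_po_duos']} "
        f"({summary['n_po_directed']} directed, {summary['n_po_undirected']} unresolved)",
        f"- trios accepted: {summary['n_trios_accepted']} of {summary['n_trios_tested']} tested",
        f"- full-sib edges (k2 > {cfg.k2_min:g}): {summary['n_fs']}",
        f"- accepted second-degree candidate hits: {summary['n_sd_accepted']}",
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))
    _update_manifest(out, "report", ["summary.json", "report.md"])


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "dedupe": stage_dedupe,
    "relate": stage_relate,
    "pedigree": stage_pedigree,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the named stages (default: all applicable) in order.

    The simulate stage runs only when no external input is configured.  A
    stage failure aborts with the stage name; earlier artifacts remain on
    disk.  Returns the summary dict when the report stage ran.
    """
    cfg.validate()
    out = _out(cfg)
    cfg.to_yaml(out / "config.yaml")
    if stages is None:
        stages = [s for s in STAGES if s != "simulate" or cfg.input_path is None]
    for stage in stages:
        if stage not in STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        log.info("running stage %s", stage)
        try:
            STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
    summary_path = out / "summary.json"
    return json.loads(summary_path.read_text()) if summary_path.exists() else {}
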
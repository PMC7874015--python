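"""Panel readers and writers: VCF 4.x (GT only) and a dosage-table TSV dialect.

Dosage tables are a pair of files: the matrix itself (first column ``sample``,
header row of marker ids, cells in {0,1,2,NA}) and a sidecar marker-metadata
TSV (columns marker_id, chrom, pos, allele_a, allele_b).  Array data commonly
arrives as such matrices; VCF alone is insufficient for merged public sets.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import MARKER_COLUMNS, MISSING, GenotypePanel, PanelError

log = logging.getLogger(__name__)


def marker_sidecar_path(table_path: str | Path) -> Path:
    """Conventional sidecar location: ``<table>.markers.tsv``."""
    p = Path(table_path)
    return p.with_name(p.name + ".markers.tsv")


def read_panel(path: str | Path, format: str = "vcf") -> GenotypePanel:
    """Read a panel from ``vcf`` or ``dosage_table`` format."""
    if format == "vcf":
        return read_vcf(path)
    if format == "dosage_table":
        return read_dosage_table(path)
    raise ValueError(f"unknown format {format!r}")


def write_panel(panel: GenotypePanel, path: str | Path, format: str = "vcf") -> None:
    if format == "vcf":
        write_vcf(panel, path)
    elif format == "dosage_table":
        write_dosage_table(panel, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# -- VCF ---------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read diploid biallelic SNPs from a VCF; dosage = count of ALT copies.

    Multiallelic or non-SNP records are skipped with a logged count; half
    calls become missing.
    """
    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise PanelError(f"{path}: duplicate sample names in VCF header")
    rows = []
    meta = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        gt = variant.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}"
        meta.append((vid, str(variant.CHROM), int(variant.POS), variant.REF, variant.ALT[0]))
    if n_skipped:
        log.info("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    if not rows:
        raise PanelError(f"{path}: no biallelic SNP records")
    markers = pd.DataFrame(
        meta, columns=["marker_id", *MARKER_COLUMNS]
    ).set_index("marker_id")
    if not markers.index.is_unique:
        raise PanelError(f"{path}: duplicate marker ids")
    dosages = np.vstack(rows).T  # markers-major -> samples x markers
    return GenotypePanel(samples, markers, dosages)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT as the only FORMAT field."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(panel.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for j, (mid, row) in enumerate(panel.markers.iterrows()):
            calls = "\t".join(gt_map[int(d)] for d in panel.dosages[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{mid}\t{row['allele_a']}\t"
                f"{row['allele_b']}\t.\t.\t.\tGT\t{calls}\n"
            )


# -- dosage table ------------------------------------------------------------


def read_dosage_table(path: str | Path, markers_path: str | Path | None = None) -> GenotypePanel:
    if markers_path is None:
        markers_path = marker_sidecar_path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelError(f"{path}: cannot parse dosage table: {exc}") from exc
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise PanelError(f"{path}: duplicate sample name(s) {dupes}")
    markers = pd.read_csv(markers_path, sep="\t", dtype={"chrom": str}).set_index("marker_id")
    missing_cols = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise PanelError(f"{markers_path}: lacks columns {missing_cols}")
    if list(table.columns) != list(markers.index):
        raise PanelError(f"{path}: marker columns do not match sidecar {markers_path}")
    values = table.to_numpy()
    dosages = np.full(values.shape, MISSING, dtype=np.int8)
    for code, d in (("0", 0), ("1", 1), ("2", 2)):
        dosages[values == code] = d
    unknown = ~np.isin(values, ("0", "1", "2", "NA")) & ~pd.isna(values)
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise PanelError(
            f"{path}: invalid cell {values[i, j]!r} at sample "
            f"{table.index[i]!r}, marker {table.columns[j]!r} (line {i + 2})"
        )
    return GenotypePanel(list(table.index), markers, dosages)


def write_dosage_table(panel: GenotypePanel, path: str | Path) -> None:
    values = panel.dosages.astype(object)
    out = pd.DataFrame(values, index=panel.samples, columns=panel.markers.index)
    out = out.where(out != MISSING, other="NA")
    out.index.name = "sample"
    out.to_csv(path, sep="\t")
    markers = panel.markers[MARKER_COLUMNS].copy()
    markers.index.name = "marker_id"
    markers.to_csv(marker_sidecar_path(path), sep="\t")


# -- merging -----------------------------------------------------------------


def merge_panels(panels: list[GenotypePanel]) -> tuple[GenotypePanel, pd.DataFrame]:
    """Merge panels on the intersection of marker ids.

    Allele orientation is reconciled by the (allele_a, allele_b) labels: a
    panel whose labels are swapped for a marker has dosages flipped d -> 2-d.
    Markers with irreconcilable labels are dropped and reported.  Duplicate
    sample names across panels are suffixed ``__2``, ``__3``, ... and reported.

    Returns (merged panel, report) where the report has one row per dropped
    marker or renamed sample.
    """
    if len(panels) < 2:
        raise ValueError("need at least two panels to merge")
    common = set(panels[0].markers.index)
    for p in panels[1:]:
        common &= set(p.markers.index)
    if not common:
        raise PanelError("empty marker intersection")
    # keep the first panel's marker order
    order = [m for m in panels[0].markers.index if m in common]
    ref = panels[0].subset_markers(order)
    report_rows: list[dict] = []

    aligned = [ref]
    dropped: set[str] = set()
    for k, p in enumerate(panels[1:], start=2):
        sub = p.subset_markers(order)
        same = (sub.markers["allele_a"].to_numpy() == ref.markers["allele_a"].to_numpy()) & (
            sub.markers["allele_b"].to_numpy() == ref.markers["allele_b"].to_numpy()
        )
        swapped = (sub.markers["allele_a"].to_numpy() == ref.markers["allele_b"].to_numpy()) & (
            sub.markers["allele_b"].to_numpy() == ref.markers["allele_a"].to_numpy()
        )
        bad = ~(same | swapped)
        for mid in np.asarray(order)[bad]:
            if mid not in dropped:
                dropped.add(mid)
                report_rows.append(
                    {"entity": mid, "kind": "marker", "action": "dropped",
                     "reason": f"irreconcilable allele labels (panel {k})"}
                )
        flip_ids = list(np.asarray(order)[swapped])
        if flip_ids:
            sub = sub.flip_markers(flip_ids)
        aligned.append(sub)

    keep = [m for m in order if m not in dropped]
    if not keep:
        raise PanelError("no markers with reconcilable allele labels")
    aligned = [p.subset_markers(keep) for p in aligned]

    seen: dict[str, int] = {}
    names: list[str] = []
    for p in aligned:
        for s in p.samples:
            if s in seen:
                seen[s] += 1
                new = f"{s}__{seen[s]}"
                report_rows.append(
                    {"entity": s, "kind": "sample", "action": f"renamed to {new}",
                     "reason": "duplicate sample name across panels"}
                )
                names.append(new)
            else:
                seen[s] = 1
                names.append(s)
    dosages = np.vstack([p.dosages for p in aligned])
    merged = GenotypePanel(names, aligned[0].markers.copy(), dosages)
    report = pd.DataFrame(report_rows, columns=["entity", "kind", "action", "reason"])
    return merged, report
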
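"""Shared fixtures: hand-built micro panels and multi-seed scenario runs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import grapekin as gk

RECOVERY_SEEDS = list(range(1, 11))


def tiny_panel(dosages, samples=None, chrom="chr01") -> gk.GenotypePanel:
    """Panel from a dense (samples x markers) list; -1 = missing."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    markers = [
        gk.Marker(f"m{j + 1}", chrom, 10 * (j + 1), "A", "G") for j in range(m)
    ]
    return gk.make_panel(samples, markers, d)


@pytest.fixture
def trio_panel() -> gk.GenotypePanel:
    """Mother (0), father (2), child (forced het 1) plus an outlier."""
    return tiny_panel(
        [
            [0, 0, 2, 1, 0],
            [2, 2, 2, 1, 0],
            [1, 1, 2, 1, 0],
            [2, 2, 0, 1, 2],
        ],
        samples=["mother", "father", "child", "other"],
    )


@dataclass
class ChainResult:
    """Everything downstream of one standard-scenario panel."""

    scenario: gk.Scenario
    clusters: list
    mismatch: gk.MismatchMatrix
    panel_dedup: gk.GenotypePanel
    panel_parentage: gk.GenotypePanel
    pruned: gk.GenotypePanel
    duos: list
    ibd: pd.DataFrame
    trios_accepted: list
    trios_tested: list
    sd_results: list
    sd_counts: dict
    graph: gk.PedigreeGraph

    def found_clone_pairs(self) -> set[frozenset]:
        pairs = set()
        for c in self.clusters:
            for i in range(len(c.members)):
                for j in range(i + 1, len(c.members)):
                    pairs.add(frozenset((c.members[i], c.members[j])))
        return pairs

    def found_po_pairs(self) -> set[frozenset]:
        return {e.pair for e in self.duos}

    def found_trios(self) -> set[tuple]:
        return {
            (t.offspring, frozenset((t.parent1, t.parent2)))
            for t in self.trios_accepted
        }


def run_chain(scenario: gk.Scenario) -> ChainResult:
    """The pipeline's analysis sequence, in memory, at default thresholds."""
    panel = scenario.panel
    mm = gk.pairwise_mismatch(panel)
    clusters = gk.cluster_identicals(mm, 0.12, panel)
    deduped, _ = gk.dedupe(panel, clusters)
    panel_qc, _ = gk.filter_markers(deduped, 0.01, 0.05)
    panel_par, _ = gk.filter_individuals(panel_qc, preset="parentage")
    pruned, _ = gk.ld_prune(panel_par)
    duos, ibd = gk.find_po_duos(panel_par, 0.03, pruned_panel=pruned)
    trios_acc, trios_all = gk.find_trios(panel_par, duos, 0.002)
    fs_edges = gk.find_fullsibs(ibd, duos, 0.3)
    sd_results, sd_counts = gk.sd_scan_duos(panel_par, duos, trios_acc, fs_edges)
    graph = gk.infer_directions(duos, trios_acc, fs_edges, sd_counts)
    return ChainResult(
        scenario, clusters, mm, deduped, panel_par, pruned, duos, ibd,
        trios_acc, trios_all, sd_results, sd_counts, graph,
    )


@pytest.fixture(scope="session")
def scenario() -> gk.Scenario:
    return gk.standard_scenario(seed=1)


@pytest.fixture(scope="session")
def chain(scenario) -> ChainResult:
    return run_chain(scenario)


@pytest.fixture(scope="session")
def clean_scenario() -> gk.Scenario:
    """Error- and missingness-free scenario for the exact (epsilon = 0) checks."""
    return gk.standard_scenario(seed=1, genotype_error_rate=0.0, missing_rate=0.0)


@pytest.fixture(scope="session")
def recovery_runs() -> list[ChainResult]:
    """Full analysis chains over the ten standard-scenario seeds."""
    return [run_chain(gk.standard_scenario(seed=s)) for s in RECOVERY_SEEDS]
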
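"""Duplicate-accession detection, identity clustering and name cross-tabs.

Clonal germplasm collections hold many duplicated genotypes (clones,
repository overlaps, mislabelled accessions).  Pairwise genotype mismatch is
strongly bimodal: identical material differs only by genotyping error (a
fraction of a percent), while distinct varieties differ at >10% of markers.
Accessions below a mismatch threshold are grouped into identity clusters;
crossing clusters with accession names flags synonym candidates (one
genotype, several names) and homonym candidates (one name, several
genotypes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class MismatchMatrix:
    """Pairwise percent mismatch over pairwise-complete markers.

    ``percent`` is symmetric with zero diagonal, NaN where no markers are
    comparable; ``n_compared`` counts the pairwise-complete markers; pairs
    with fewer than ``min_compared`` markers are flagged unreliable.
    """

    samples: list[str]
    percent: np.ndarray
    n_compared: np.ndarray
    min_compared: int = 500

    @property
    def reliable(self) -> np.ndarray:
        return self.n_compared >= self.min_compared

    def pair(self, id1: str, id2: str) -> tuple[float, int]:
        i, j = self.samples.index(id1), self.samples.index(id2)
        return float(self.percent[i, j]), int(self.n_compared[i, j])

    def to_frame(self) -> pd.DataFrame:
        iu = np.triu_indices(len(self.samples), k=1)
        s = np.asarray(self.samples)
        return pd.DataFrame(
            {
                "id1": s[iu[0]],
                "id2": s[iu[1]],
                "mismatch_pct": self.percent[iu],
                "n_compared": self.n_compared[iu].astype(np.int64),
                "reliable": self.reliable[iu],
            }
        )


@dataclass
class IdentityCluster:
    """A group of accessions with pairwise mismatch below the identity
    threshold; the representative is the least-missing member."""

    members: list[str]
    representative: str
    max_internal_mismatch: float
    names: dict[str, str] = field(default_factory=dict)


def pairwise_mismatch(panel: GenotypePanel, min_compared: int = 500) -> MismatchMatrix:
    """Percent of pairwise-complete markers with unequal dosage, all pairs."""
    if panel.n_samples < 2:
        raise ValueError("need at least two individuals")
    d = panel.dosages
    called = panel.called().astype(np.float64)
    match = np.zeros((panel.n_samples, panel.n_samples))
    for v in (0, 1, 2):
        g = (d == v).astype(np.float64)
        match += g @ g.T
    n_compared = called @ called.T
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = 100.0 * (1.0 - match / n_compared)
    percent[n_compared == 0] = np.nan
    np.fill_diagonal(percent, 0.0)
    return MismatchMatrix(
        list(panel.samples), percent, n_compared.astype(np.int64), min_compared
    )


def cluster_identicals(
    mm: MismatchMatrix,
    threshold: float = 0.12,
    panel: GenotypePanel | None = None,
) -> list[IdentityCluster]:
    """Single-linkage clustering of accessions at mismatch < threshold (%).

    Single linkage matches grouping "clusters of identical individuals"
    under a near-zero threshold, where the linkage choice is immaterial, and
    is independent of input order.  Pass ``panel`` so representatives can be
    chosen by lowest missingness (ties broken by input order).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = len(mm.samples)
    # union-find over edges strictly below the threshold
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    with np.errstate(invalid="ignore"):
        links = np.argwhere(np.triu(mm.percent < threshold, k=1))
    for i, j in links:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    if panel is not None:
        miss = {
            s: float(m)
            for s, m in zip(panel.samples, 1.0 - panel.called().mean(axis=1))
        }
    else:
        miss = {s: 0.0 for s in mm.samples}

    clusters = []
    for root in sorted(groups):
        idx = groups[root]
        members = [mm.samples[i] for i in idx]
        rep = min(members, key=lambda s: (miss[s], members.index(s)))
        if len(idx) > 1:
            sub = mm.percent[np.ix_(idx, idx)]
            max_mm = float(np.nanmax(sub[np.triu_indices(len(idx), k=1)]))
        else:
            max_mm = 0.0
        clusters.append(IdentityCluster(members, rep, max_mm))
    return clusters


def name_crosstab(
    clusters: list[IdentityCluster], names: dict[str, str] | pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Cross-tabulate identity clusters against accession variety names.

    Same cluster + different names -> synonym candidates; same name in >= 2
    clusters -> homonym candidates.  Curation labels (wrong denomination,
    misnomer) are human decisions and are emitted as a blank column.
    """
    if isinstance(names, pd.DataFrame):
        names = dict(zip(names.iloc[:, 0], names.iloc[:, 1]))
    for cl in clusters:
        for m in cl.members:
            if m not in names:
                raise ValueError(f"accession {m!r} has no name")
        cl.names = {m: names[m] for m in cl.members}

    syn_rows = []
    for ci, cl in enumerate(clusters):
        distinct = sorted(set(cl.names.values()))
        if len(distinct) > 1:
            syn_rows.append(
                {
                    "cluster": ci,
                    "n_members": len(cl.members),
                    "names": "; ".join(distinct),
                    "curation": "",
                }
            )
    by_name: dict[str, set[int]] = {}
    for ci, cl in enumerate(clusters):
        for nm in set(cl.names.values()):
            by_name.setdefault(nm, set()).add(ci)
    hom_rows = [
        {"name": nm, "n_clusters": len(cis),
         "clusters": "; ".join(str(c) for c in sorted(cis)), "curation": ""}
        for nm, cis in sorted(by_name.items())
        if len(cis) > 1
    ]
    return {
        "synonym_candidates": pd.DataFrame(
            syn_rows, columns=["cluster", "n_members", "names", "curation"]
        ),
        "homonym_candidates": pd.DataFrame(
            hom_rows, columns=["name", "n_clusters", "clusters", "curation"]
        ),
    }


def dedupe(
    panel: GenotypePanel, clusters: list[IdentityCluster]
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Keep one representative per identity cluster.

    Returns (deduplicated panel, mapping of member -> representative).
    Idempotent: running again on the result is a no-op.
    """
    clustered = {m for cl in clusters for m in cl.members}
    unknown = clustered - set(panel.samples)
    if unknown:
        raise ValueError(f"clusters reference samples not in panel: {sorted(unknown)[:5]}")
    keep = []
    rows = []
    reps = {cl.representative for cl in clusters}
    for s in panel.samples:
        if s not in clustered or s in reps:
            keep.append(s)
    for cl in clusters:
        for m in cl.members:
            rows.append({"member": m, "representative": cl.representative,
                         "kept": m == cl.representative})
    mapping = pd.DataFrame(rows, columns=["member", "representative", "kept"])
    return panel.subset_samples(keep), mapping
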
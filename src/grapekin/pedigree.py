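"""Pedigree inference: PO duos, trios, full sibs, the conditional
second-degree (half-sibship) scan, grandparent tests, direction inference and
network assembly.

The second-degree (SD) scan is the workhorse for missing-parent lineages.
Given an accepted parent-offspring duo and an assumed direction, the markers
where the assumed parent is homozygous and the offspring heterozygous carry an
*obligate allele*: the offspring allele the assumed parent cannot have
transmitted, which must descend from the missing parent.  A candidate that is
a half-sib, grandparent or avuncular relative of the offspring through that
missing parent carries each obligate allele with probability 1/2 over and
above the population carrier background, so its observed carrier fraction
f_obs shows a large standardized excess z over the Hardy-Weinberg expectation
f_exp.  Running the scan in both directions of an unresolved duo also hints
at the true direction: only the offspring side has a missing-parent lineage
for its genotyped relatives to light up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel
from .qc import allele_frequencies
from .relatedness import TrioResult, mendel_errors_trio, pairwise_duo_errors, pairwise_ibd

log = logging.getLogger(__name__)


@dataclass
class RelationshipEdge:
    id1: str
    id2: str
    relation: str  # PO | FS | SD-candidate
    k0: float = float("nan")
    k1: float = float("nan")
    k2: float = float("nan")
    kinship: float = float("nan")
    duo_errors: int = -1
    direction: tuple[str, str] | None = None  # (parent, child)
    evidence: str = ""  # how the direction was resolved
    trio_id: str = ""

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.id1, self.id2))


@dataclass(frozen=True)
class SDScanResult:
    parent_assumed: str
    offspring: str
    candidate: str
    n_informative: int
    f_obs: float
    f_exp: float
    z: float
    accepted: bool


@dataclass(frozen=True)
class GrandparentTest:
    parent_assumed: str
    offspring: str
    g1: str
    g2: str
    n_informative: int
    incompatibilities: int

    @property
    def rate(self) -> float:
        return self.incompatibilities / self.n_informative if self.n_informative else float("nan")


# -- PO duos, trios, full sibs -------------------------------------------------


def find_po_duos(
    panel: GenotypePanel,
    k0_max: float = 0.03,
    pruned_panel: GenotypePanel | None = None,
    freqs: np.ndarray | None = None,
) -> tuple[list[RelationshipEdge], pd.DataFrame]:
    """All pairs with k0 < k0_max, annotated with duo Mendelian errors.

    IBD is estimated on ``pruned_panel`` (default: ``panel``) so the method-
    of-moments sees quasi-independent loci; duo errors are counted on the
    full ``panel``.  Returns (edges, the all-pairs IBD table) — the table's
    k0 column is the histogram the bimodal-gap inspection needs.
    """
    ibd_panel = pruned_panel if pruned_panel is not None else panel
    ibd = pairwise_ibd(ibd_panel, freqs=freqs, include_duo_errors=False)
    errors = pairwise_duo_errors(panel)
    ibd = ibd.merge(
        errors.rename(columns={"n_valid": "n_valid_errors"}), on=["id1", "id2"], how="left"
    )
    edges = []
    for row in ibd.itertuples():
        if row.k0 < k0_max:
            edges.append(
                RelationshipEdge(
                    row.id1, row.id2, "PO",
                    k0=row.k0, k1=row.k1, k2=row.k2, kinship=row.kinship,
                    duo_errors=int(row.duo_errors),
                )
            )
    return edges, ibd


def find_trios(
    panel: GenotypePanel,
    duos: list[RelationshipEdge],
    max_error_rate: float = 0.002,
) -> tuple[list[TrioResult], list[TrioResult]]:
    """Test every unordered pair of an individual's PO partners as its parents.

    A trio is accepted when its Mendelian error rate is at most
    ``max_error_rate`` (the true/false trio gap is two orders of magnitude,
    so the threshold is not delicate).  Returns (accepted, all tested).
    """
    partners: dict[str, list[str]] = {}
    for e in duos:
        partners.setdefault(e.id1, []).append(e.id2)
        partners.setdefault(e.id2, []).append(e.id1)
    accepted, tested = [], []
    for off, ps in sorted(partners.items()):
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                res = mendel_errors_trio(panel, off, ps[i], ps[j])
                tested.append(res)
                if res.n_valid and res.error_rate <= max_error_rate:
                    accepted.append(res)
    return accepted, tested


def find_fullsibs(
    ibd: pd.DataFrame,
    po_edges: list[RelationshipEdge],
    k2_min: float = 0.3,
) -> list[RelationshipEdge]:
    """Non-PO pairs with k2 > k2_min flagged as well-supported full sibs.

    The conservative default follows germplasm practice where background
    relatedness blurs the FS/half-sib boundary; on pedigrees with unrelated
    founders the FS k2 estimate concentrates near its expectation 0.25, so a
    lower cutoff is appropriate there.
    """
    po_pairs = {e.pair for e in po_edges}
    edges = []
    for row in ibd.itertuples():
        pair = frozenset((row.id1, row.id2))
        if pair not in po_pairs and row.k2 > k2_min:
            edges.append(
                RelationshipEdge(
                    row.id1, row.id2, "FS",
                    k0=row.k0, k1=row.k1, k2=row.k2, kinship=row.kinship,
                )
            )
    return edges


# -- conditional second-degree scan -------------------------------------------


def _informative_markers(
    parent_d: np.ndarray, off_d: np.ndarray, both_hom_classes: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Markers with parent homozygous and offspring heterozygous.

    Returns (mask, obligate_is_b) where obligate_is_b says whether the
    obligate allele (absent from the assumed parent) is the B allele.  With
    ``both_hom_classes`` False only the parent-AA class is used (the literal
    single-sided variant).
    """
    het = off_d == 1
    aa = (parent_d == 0) & het
    bb = (parent_d == 2) & het
    mask = aa | bb if both_hom_classes else aa
    return mask, aa


def sd_scan(
    panel: GenotypePanel,
    po_pair: tuple[str, str],
    direction: tuple[str, str],
    candidates: list[str] | None = None,
    freqs: np.ndarray | None = None,
    min_informative: int = 100,
    z_min: float = 4.0,
    min_excess: float = 0.15,
    both_hom_classes: bool = True,
) -> list[SDScanResult]:
    """Scan candidates for second-degree relatedness to the offspring through
    its missing parent, conditional on a focal PO duo.

    ``direction`` = (assumed parent, offspring) and must be the ``po_pair``
    in some order.  For each candidate, f_obs is the fraction of informative
    markers at which it carries the obligate allele; f_exp is the
    Hardy-Weinberg carrier expectation averaged over those markers; a
    candidate is accepted when z >= z_min AND f_obs - f_exp >= min_excess,
    with at least ``min_informative`` markers (two-sided guard against
    small-n flukes and large-n trivial excesses).  Candidates with fewer
    informative comparisons are suppressed (not returned).
    """
    if set(direction) != set(po_pair):
        raise ValueError("direction must order the po_pair itself")
    parent, off = direction
    if freqs is None:
        freqs = allele_frequencies(panel)
    pd_ = panel.dosages[panel.sample_index(parent)]
    od = panel.dosages[panel.sample_index(off)]
    called = (pd_ != MISSING) & (od != MISSING)
    mask, obligate_b = _informative_markers(pd_, od, both_hom_classes)
    mask &= called
    if candidates is None:
        candidates = [s for s in panel.samples if s not in (parent, off)]
    results = []
    p = np.asarray(freqs, dtype=np.float64)
    for cand in candidates:
        if cand in (parent, off):
            continue
        cd = panel.dosages[panel.sample_index(cand)]
        use = mask & (cd != MISSING) & np.isfinite(p)
        n_inf = int(use.sum())
        if n_inf < min_informative:
            continue
        ob_b = obligate_b[use]
        carries = np.where(ob_b, cd[use] >= 1, cd[use] <= 1)
        f_obs = float(carries.mean())
        pv = p[use]
        carrier_exp = np.where(ob_b, 1.0 - (1.0 - pv) ** 2, 1.0 - pv**2)
        f_exp = float(carrier_exp.mean())
        se = np.sqrt(max(f_exp * (1.0 - f_exp), 1e-12) / n_inf)
        z = (f_obs - f_exp) / se
        accepted = (z >= z_min) and (f_obs - f_exp >= min_excess)
        results.append(
            SDScanResult(parent, off, cand, n_inf, f_obs, f_exp, float(z), bool(accepted))
        )
    return results


def test_grandparents(
    panel: GenotypePanel,
    po_pair: tuple[str, str],
    direction: tuple[str, str],
    g1: str,
    g2: str,
    max_rate: float = 0.01,
) -> GrandparentTest:
    """Test a candidate grandparent pair (parents of the missing parent).

    Over the informative markers of the duo, an incompatibility is a marker
    whose obligate allele is carried by neither g1 nor g2 — impossible (bar
    genotyping error) if they really are the missing parent's parents, since
    the transmitted allele must descend from one of them.
    """
    if set(direction) != set(po_pair):
        raise ValueError("direction must order the po_pair itself")
    parent, off = direction
    pd_ = panel.dosages[panel.sample_index(parent)]
    od = panel.dosages[panel.sample_index(off)]
    g1d = panel.dosages[panel.sample_index(g1)]
    g2d = panel.dosages[panel.sample_index(g2)]
    mask, obligate_b = _informative_markers(pd_, od)
    mask &= (pd_ != MISSING) & (od != MISSING) & (g1d != MISSING) & (g2d != MISSING)
    ob_b = obligate_b[mask]
    g1c = np.where(ob_b, g1d[mask] >= 1, g1d[mask] <= 1)
    g2c = np.where(ob_b, g2d[mask] >= 1, g2d[mask] <= 1)
    incompat = int((~g1c & ~g2c).sum())
    return GrandparentTest(parent, off, g1, g2, int(mask.sum()), incompat)


def grandparent_background(
    panel: GenotypePanel,
    po_pair: tuple[str, str],
    direction: tuple[str, str],
    n_permutations: int = 100,
    rng: np.random.Generator | int = 0,
    exclude: set[str] | None = None,
) -> np.ndarray:
    """Empirical incompatibility rates of random candidate pairs.

    Serves as the acceptance background for :func:`test_grandparents`: a true
    grandparent pair should fall far below this distribution.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pool = [s for s in panel.samples if s not in set(po_pair) | set(exclude or ())]
    rates = []
    for _ in range(n_permutations):
        g1, g2 = rng.choice(pool, size=2, replace=False)
        t = test_grandparents(panel, po_pair, direction, str(g1), str(g2))
        rates.append(t.rate)
    return np.asarray(rates)


def sd_scan_duos(
    panel: GenotypePanel,
    duos: list[RelationshipEdge],
    trios: list[TrioResult],
    fs_edges: list[RelationshipEdge] | None = None,
    freqs: np.ndarray | None = None,
    **scan_kwargs,
) -> tuple[list[SDScanResult], dict[tuple[str, str], int]]:
    """Run the SD scan in both directions for every duo without a trio.

    Candidates already first-degree to the assumed offspring (its PO, FS or
    clone partners) are excluded: they carry the offspring's alleles at ~1/2
    excess regardless of which parent transmitted them, so counting them
    would manufacture missing-parent evidence in the wrong direction too.

    Returns (all scan results, accepted-candidate count per direction) —
    the count dict feeds :func:`infer_directions` rule 3.
    """
    if freqs is None:
        freqs = allele_frequencies(panel)
    in_trio: set[frozenset[str]] = set()
    for t in trios:
        in_trio.add(frozenset((t.offspring, t.parent1)))
        in_trio.add(frozenset((t.offspring, t.parent2)))
    first_degree: dict[str, set[str]] = {}
    for e in duos:
        first_degree.setdefault(e.id1, set()).add(e.id2)
        first_degree.setdefault(e.id2, set()).add(e.id1)
    for e in fs_edges or ():
        first_degree.setdefault(e.id1, set()).add(e.id2)
        first_degree.setdefault(e.id2, set()).add(e.id1)

    results: list[SDScanResult] = []
    counts: dict[tuple[str, str], int] = {}
    for e in duos:
        if e.pair in in_trio:
            continue
        for parent, off in ((e.id1, e.id2), (e.id2, e.id1)):
            cands = [
                s for s in panel.samples
                if s not in (parent, off) and s not in first_degree.get(off, ())
            ]
            res = sd_scan(
                panel, (e.id1, e.id2), (parent, off), cands, freqs=freqs, **scan_kwargs
            )
            results.extend(res)
            counts[(parent, off)] = sum(r.accepted for r in res)
    return results, counts


# -- direction inference and the network --------------------------------------


@dataclass
class PedigreeGraph:
    """Deduplicated varieties as nodes; PO/FS edges with direction metadata."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_edge(self, edge: RelationshipEdge) -> None:
        if edge.id1 == edge.id2:
            raise ValueError("self edges are not allowed")
        self.graph.add_node(edge.id1)
        self.graph.add_node(edge.id2)
        key = (edge.id1, edge.id2)
        attrs = {
            "relation": edge.relation,
            "k0": edge.k0, "k1": edge.k1, "k2": edge.k2, "kinship": edge.kinship,
            "duo_errors": edge.duo_errors,
            "direction": "" if edge.direction is None else f"{edge.direction[0]}->{edge.direction[1]}",
            "evidence": edge.evidence,
            "trio_id": edge.trio_id,
        }
        if self.graph.has_edge(*key) and self.graph.edges[key]["relation"] == edge.relation:
            raise ValueError(f"duplicate {edge.relation} edge {key}")
        self.graph.add_edge(*key, **attrs)

    def edges(self) -> list[dict]:
        """Edge records with canonical (sorted) node order; the direction
        field, not the column order, carries parent/child polarity."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append({"id1": a, "id2": b, **data})
        return out


def infer_directions(
    po_edges: list[RelationshipEdge],
    trios: list[TrioResult],
    fs_edges: list[RelationshipEdge],
    sd_accept_counts: dict[tuple[str, str], int] | None = None,
    m_min: int = 2,
) -> PedigreeGraph:
    """Resolve PO edge directions by priority: trios, then the full-sib rule,
    then second-degree evidence.

    1. Trio membership directs both parental edges toward the offspring.
    2. FS rule: if A has a full sib C and C is PO with none of A's PO
       partners, A is the parent in all of A's unresolved PO edges (were A
       the offspring, its sib would be related to A's parent too).
    3. SD rule: ``sd_accept_counts[(parent, offspring)]`` gives the number of
       accepted SD candidates when the duo is scanned in that direction; a
       direction is adopted when it reaches ``m_min`` accepted candidates
       and the opposite direction does not.

    Contradictory rule outcomes leave the edge undirected with the conflict
    logged.  Soundness over completeness: edges may remain undirected.
    """
    g = PedigreeGraph()
    by_pair: dict[frozenset[str], RelationshipEdge] = {}
    for e in po_edges:
        e.direction, e.evidence = None, ""
        by_pair[e.pair] = e

    # rule 1: trios
    for t_i, t in enumerate(trios):
        for parent in (t.parent1, t.parent2):
            e = by_pair.get(frozenset((t.offspring, parent)))
            if e is None:
                continue
            want = (parent, t.offspring)
            if e.direction is not None and e.direction != want:
                log.warning("trio %s contradicts direction of %s; leaving undirected", t, e)
                e.direction, e.evidence = None, "conflict"
                continue
            e.direction, e.evidence = want, "trio"
            e.trio_id = e.trio_id or f"trio{t_i}"

    # rule 2: full sibs
    partners: dict[str, set[str]] = {}
    for e in po_edges:
        partners.setdefault(e.id1, set()).add(e.id2)
        partners.setdefault(e.id2, set()).add(e.id1)
    for fs in fs_edges:
        for a, c in ((fs.id1, fs.id2), (fs.id2, fs.id1)):
            if partners.get(c, set()) & partners.get(a, set()):
                continue  # the sib is PO with one of A's partners: no call
            for other in partners.get(a, ()):
                e = by_pair[frozenset((a, other))]
                if e.direction is not None or e.evidence == "conflict":
                    continue  # only unresolved duos; rule 1 outranks
                e.direction, e.evidence = (a, other), "fs-rule"

    # rule 3: SD evidence
    if sd_accept_counts:
        for e in po_edges:
            if e.direction is not None or e.evidence == "conflict":
                continue
            fwd = sd_accept_counts.get((e.id1, e.id2), 0)
            rev = sd_accept_counts.get((e.id2, e.id1), 0)
            if fwd >= m_min and rev < m_min:
                e.direction, e.evidence = (e.id1, e.id2), "sd-rule"
            elif rev >= m_min and fwd < m_min:
                e.direction, e.evidence = (e.id2, e.id1), "sd-rule"
            elif fwd >= m_min and rev >= m_min:
                log.warning("SD evidence in both directions for %s-%s", e.id1, e.id2)
                e.evidence = "conflict"

    for e in po_edges:
        g.add_edge(e)
    for e in fs_edges:
        g.add_edge(e)
    return g


def kinship_neighbors(
    ibd: pd.DataFrame,
    individual: str,
    phi_min: float = 0.13,
    classified: set[frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Unclassified close relatives of one individual, ranked by kinship.

    Pairs already explained as PO/FS/clone are excluded; what remains is
    labelled an unclassified close relative (second degree or closer, but the
    kinship coefficient alone cannot tell which, nor ancestor from
    descendant).
    """
    classified = classified or set()
    rows = []
    for row in ibd.itertuples():
        if individual not in (row.id1, row.id2):
            continue
        other = row.id2 if row.id1 == individual else row.id1
        if frozenset((individual, other)) in classified:
            continue
        if row.kinship > phi_min:
            rows.append({"individual": other, "kinship": row.kinship,
                         "k0": row.k0, "k1": row.k1, "k2": row.k2,
                         "label": "unclassified close relative"})
    out = pd.DataFrame(rows, columns=["individual", "kinship", "k0", "k1", "k2", "label"])
    return out.sort_values("kinship", ascending=False).reset_index(drop=True)


# -- export --------------------------------------------------------------------

EDGE_COLUMNS = [
    "id1", "id2", "relation", "direction", "k0", "k1", "k2", "kinship",
    "duo_errors", "trio_id", "evidence",
]


def export_network(graph: PedigreeGraph, path: str | Path, format: str = "edge_tsv") -> None:
    """Write the network as edge TSV (lossless), GraphML or DOT."""
    path = Path(path)
    if format == "edge_tsv":
        pd.DataFrame(graph.edges(), columns=EDGE_COLUMNS).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    elif format == "graphml":
        nx.write_graphml(graph.graph, path)
    elif format == "dot":
        with open(path, "w") as fh:
            fh.write("digraph pedigree {\n")
            for node in graph.graph.nodes:
                fh.write(f'  "{node}";\n')
            for u, v, data in graph.graph.edges(data=True):
                if data.get("direction"):
                    a, b = data["direction"].split("->")
                    attrs = f'label="{data["relation"]}"'
                else:
                    a, b = u, v
                    attrs = f'label="{data["relation"]}", dir=none'
                fh.write(f'  "{a}" -> "{b}" [{attrs}];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_edge_tsv(path: str | Path) -> PedigreeGraph:
    """Inverse of edge_tsv export (round-trips all support fields)."""
    df = pd.read_csv(
        path, sep="\t", float_precision="round_trip",
        dtype={"trio_id": str, "evidence": str, "direction": str},
    )
    g = PedigreeGraph()
    for row in df.itertuples():
        direction = None
        if isinstance(row.direction, str) and "->" in row.direction:
            a, b = row.direction.split("->")
            direction = (a, b)
        g.add_edge(
            RelationshipEdge(
                row.id1, row.id2, row.relation,
                k0=row.k0, k1=row.k1, k2=row.k2, kinship=row.kinship,
                duo_errors=int(row.duo_errors),
                direction=direction,
                evidence="" if pd.isna(row.evidence) else str(row.evidence),
                trio_id="" if pd.isna(row.trio_id) else str(row.trio_id),
            )
        )
    return g
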
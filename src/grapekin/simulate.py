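"""Synthetic pedigree simulator with known ground truth.

Generates genotype panels that emulate the statistical structure of an
18K-array-like germplasm panel after QC: several thousand unlinked biallelic
markers, founder genotypes in Hardy-Weinberg proportions at frequencies drawn
from a MAF sampler tuned for ~33% mean individual heterozygosity, Mendelian
gene dropping through multi-generation pedigrees containing clones, selfings,
trios, full sibs and half sibs through non-genotyped parents, plus a small
symmetric genotyping-error model and random missingness.

The genotyping-error rate default (1e-4 per call) is back-calculated from two
observable anchors of such panels: clone pairs must stay below a 0.12%
pairwise-mismatch ceiling (two independently corrupted copies disagree at
rate ~ 2*eps, and the Poisson tail over ~6.5k markers must clear the strict
threshold), and true parent-parent-offspring trios should show only single-
digit Mendelian error counts at panel scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import MARKER_COLUMNS, MISSING, GenotypePanel

# relationship labels returned by the truth oracle
CLONE = "CLONE"
PO = "PO"
SELF_OFFSPRING = "SELF"
FS = "FS"
HS = "HS"
GP = "GP"
AV = "AV"
UNREL = "UNREL"
OTHER = "OTHER"


# -- pedigree events ---------------------------------------------------------


@dataclass(frozen=True)
class Cross:
    parent1: str
    parent2: str
    child: str


@dataclass(frozen=True)
class Self:
    parent: str
    child: str


@dataclass(frozen=True)
class Clone:
    source: str
    copy: str


Event = Cross | Self | Clone


@dataclass
class SimulationConfig:
    """Recipe for one synthetic panel.

    ``maf_range`` is the support of the uniform sampler of per-marker minor
    allele frequencies; the minor allele is randomly assigned to A or B.  The
    default (0.05, 0.4) yields mean founder heterozygosity E[2pq] ~ 0.33,
    the panel-scale value after MAF >= 5% filtering.  ``hidden`` names
    individuals simulated but excluded from the released panel (missing
    parents and their ancestors used to create half-sibships).
    """

    n_markers: int = 6800
    n_founders: int = 40
    maf_range: tuple[float, float] = (0.05, 0.4)
    events: list[Event] = field(default_factory=list)
    genotype_error_rate: float = 1e-4
    missing_rate: float = 0.005
    seed: int = 0
    hidden: set[str] = field(default_factory=set)
    founder_prefix: str = "F"
    extra_founders: list[str] = field(default_factory=list)
    #: >1 turns on block-copying LD: founder dosage columns are duplicated
    #: within consecutive blocks of this size (perfect LD among founders),
    #: solely to exercise LD pruning.  Transmission stays per-marker
    #: independent, so the correlation decays in descendants.
    ld_block: int = 1

    def founder_names(self) -> list[str]:
        base = [f"{self.founder_prefix}{i + 1:02d}" for i in range(self.n_founders)]
        return base + list(self.extra_founders)

    def validate(self) -> None:
        if not (0 <= self.genotype_error_rate < 1 and 0 <= self.missing_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        defined = set(self.founder_names())
        for ev in self.events:
            if isinstance(ev, Cross):
                refs, new = (ev.parent1, ev.parent2), ev.child
            elif isinstance(ev, Self):
                refs, new = (ev.parent,), ev.child
            else:
                refs, new = (ev.source,), ev.copy
            for r in refs:
                if r not in defined:
                    raise ValueError(f"event references undefined individual {r!r}")
            if new in defined:
                raise ValueError(f"individual {new!r} defined twice")
            defined.add(new)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_markers": self.n_markers,
            "n_founders": self.n_founders,
            "maf_range": list(self.maf_range),
            "genotype_error_rate": self.genotype_error_rate,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "hidden": sorted(self.hidden),
            "extra_founders": list(self.extra_founders),
            "ld_block": self.ld_block,
            "events": [
                {"cross": [e.parent1, e.parent2, e.child]}
                if isinstance(e, Cross)
                else {"self": [e.parent, e.child]}
                if isinstance(e, Self)
                else {"clone": [e.source, e.copy]}
                for e in self.events
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text())
        events: list[Event] = []
        for item in doc.get("events", []):
            ((kind, args),) = item.items()
            if kind == "cross":
                events.append(Cross(*args))
            elif kind == "self":
                events.append(Self(*args))
            elif kind == "clone":
                events.append(Clone(*args))
            else:
                raise ValueError(f"unknown event kind {kind!r}")
        return cls(
            n_markers=doc["n_markers"],
            n_founders=doc["n_founders"],
            maf_range=tuple(doc["maf_range"]),
            events=events,
            genotype_error_rate=doc["genotype_error_rate"],
            missing_rate=doc["missing_rate"],
            seed=doc["seed"],
            hidden=set(doc.get("hidden", [])),
            extra_founders=list(doc.get("extra_founders", [])),
            ld_block=doc.get("ld_block", 1),
        )


# -- ground truth ------------------------------------------------------------


class TruePedigree:
    """Simulator ground truth: parent map, clone map, relationship oracle.

    ``parents`` maps child -> (parent1, parent2); selfings have
    parent1 == parent2.  ``clones`` maps copy -> source.  ``hidden`` lists
    simulated individuals absent from the released panel.
    """

    def __init__(
        self,
        parents: dict[str, tuple[str, str]],
        clones: dict[str, str],
        founders: list[str],
        hidden: set[str] | None = None,
    ):
        self.parents = dict(parents)
        self.clones = dict(clones)
        self.founders = list(founders)
        self.hidden = set(hidden or ())
        self._kin_cache: dict[tuple[str, str], float] = {}
        self._depth: dict[str, int] = {}
        for f in self.founders:
            self._depth[f] = 0
        changed = True
        while changed:  # events are topologically ordered, one pass usually
            changed = False
            for c, (p1, p2) in self.parents.items():
                if c not in self._depth and p1 in self._depth and p2 in self._depth:
                    self._depth[c] = max(self._depth[p1], self._depth[p2]) + 1
                    changed = True
        for copy, src in self.clones.items():
            self._depth[copy] = self._depth[src]

    # clone copies are genetically their source
    def _resolve(self, a: str) -> str:
        while a in self.clones:
            a = self.clones[a]
        return a

    def parent_set(self, a: str) -> set[str]:
        a = self._resolve(a)
        if a not in self.parents:
            return set()
        return {self._resolve(p) for p in self.parents[a]}

    def kinship(self, a: str, b: str) -> float:
        """Pedigree kinship coefficient (recursive; founders unrelated)."""
        a, b = self._resolve(a), self._resolve(b)
        if self._depth.get(a, 0) < self._depth.get(b, 0):
            a, b = b, a
        key = (a, b) if a <= b else (b, a)
        if key in self._kin_cache:
            return self._kin_cache[key]
        if a == b:
            if a in self.parents:
                p1, p2 = self.parents[a]
                val = 0.5 + 0.5 * self.kinship(p1, p2)
            else:
                val = 0.5
        elif a not in self.parents:  # both founders (a is the deeper one)
            val = 0.0
        else:
            p1, p2 = self.parents[a]
            val = 0.5 * (self.kinship(p1, b) + self.kinship(p2, b))
        self._kin_cache[key] = val
        return val

    def relationship(self, a: str, b: str) -> str:
        """Closest-pattern relationship label for a pair."""
        ra, rb = self._resolve(a), self._resolve(b)
        if ra == rb:
            return CLONE
        pa, pb = self.parent_set(ra), self.parent_set(rb)
        if ra in pb or rb in pa:
            child = ra if rb in pa else rb
            cp = self.parents[self._resolve(child)]
            if cp[0] == cp[1]:
                return SELF_OFFSPRING
            return PO
        if pa and pa == pb:
            return FS
        if pa and pb and len(pa & pb) == 1:
            return HS
        grand_a = {g for p in pa for g in self.parent_set(p)}
        grand_b = {g for p in pb for g in self.parent_set(p)}
        if ra in grand_b or rb in grand_a:
            return GP
        # avuncular: one is a full sib of a parent of the other
        for x, py in ((ra, pb), (rb, pa)):
            px = self.parent_set(x)
            for p in py:
                if px and px == self.parent_set(p):
                    return AV
        if self.kinship(ra, rb) == 0.0:
            return UNREL
        return OTHER

    # -- truth sets over the genotyped panel ---------------------------------

    def genotyped(self) -> list[str]:
        order = list(self.founders) + [c for c in self.parents if c not in self.founders]
        order += [c for c in self.clones]
        seen = set()
        out = []
        for n in order:
            if n not in seen and n not in self.hidden:
                seen.add(n)
                out.append(n)
        return out

    def clone_pairs(self) -> set[frozenset[str]]:
        vis = [s for s in self.genotyped()]
        groups: dict[str, list[str]] = {}
        for s in vis:
            groups.setdefault(self._resolve(s), []).append(s)
        pairs = set()
        for members in groups.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add(frozenset((members[i], members[j])))
        return pairs

    def po_pairs(self, among: list[str] | None = None) -> set[frozenset[str]]:
        """True parent-offspring pairs among the given individuals
        (default: genotyped, one representative per clone group)."""
        if among is None:
            among = self.representatives()
        among_set = set(among)
        pairs = set()
        for a in among:
            for p in self.parent_set(a):
                for cand in among_set:
                    if self._resolve(cand) == p and cand != a:
                        pairs.add(frozenset((a, cand)))
        return pairs

    def trios(self, among: list[str] | None = None) -> set[tuple[str, frozenset[str]]]:
        """(offspring, {parent1, parent2}) with both parents genotyped."""
        if among is None:
            among = self.representatives()
        by_source = {}
        for cand in among:
            by_source.setdefault(self._resolve(cand), cand)
        out = set()
        for child in among:
            ps = self.parents.get(self._resolve(child))
            if not ps or ps[0] == ps[1]:
                continue
            p1, p2 = (self._resolve(p) for p in ps)
            if p1 in by_source and p2 in by_source:
                out.add((child, frozenset((by_source[p1], by_source[p2]))))
        return out

    def fs_pairs(self, among: list[str] | None = None) -> set[frozenset[str]]:
        if among is None:
            among = self.representatives()
        out = set()
        for i, a in enumerate(among):
            for b in among[i + 1 :]:
                if self.relationship(a, b) == FS:
                    out.add(frozenset((a, b)))
        return out

    def stand_in(self, name: str, samples: list[str]) -> str | None:
        """The member of ``samples`` genetically identical to ``name``
        (itself or a clone), or None if absent."""
        src = self._resolve(name)
        for s in samples:
            if self._resolve(s) == src:
                return s
        return None

    def representatives(self) -> list[str]:
        """Genotyped individuals, one per clone group (the source if present)."""
        vis = self.genotyped()
        vis_set = set(vis)
        out = []
        for s in vis:
            src = self._resolve(s)
            if src in vis_set:
                if s == src:
                    out.append(s)
            else:
                # source hidden: keep first copy encountered
                if all(self._resolve(t) != src for t in out):
                    out.append(s)
        return out

    def to_tsv(self, parents_path: str | Path, clones_path: str | Path) -> None:
        pd.DataFrame(
            [(c, p1, p2) for c, (p1, p2) in self.parents.items()],
            columns=["child", "parent1", "parent2"],
        ).to_csv(parents_path, sep="\t", index=False)
        pd.DataFrame(
            list(self.clones.items()), columns=["copy", "source"]
        ).to_csv(clones_path, sep="\t", index=False)


# -- simulation operations ---------------------------------------------------


def _marker_table(n_markers: int) -> pd.DataFrame:
    """Synthetic marker map: 19 chromosomes, evenly spaced positions."""
    n_chrom = 19
    per = int(np.ceil(n_markers / n_chrom))
    chroms, pos, ids = [], [], []
    k = 0
    for c in range(1, n_chrom + 1):
        for i in range(per):
            if k >= n_markers:
                break
            chroms.append(f"chr{c:02d}")
            pos.append(10_000 * (i + 1))
            ids.append(f"snp{k + 1:05d}")
            k += 1
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos, "allele_a": "A", "allele_b": "G"},
        index=pd.Index(ids, name="marker_id"),
    )


def sample_b_frequencies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-marker B-allele frequency: MAF ~ U(maf_range), minor allele
    assigned to A or B with equal probability."""
    maf = rng.uniform(*config.maf_range, size=config.n_markers)
    flip = rng.random(config.n_markers) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def simulate_founders(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypePanel, np.ndarray]:
    """Founder genotypes under Hardy-Weinberg at sampled frequencies.

    Returns (panel, true B-allele frequencies).  Reproducible for a fixed
    config seed when ``rng`` is not supplied.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = config.founder_names()
    p = sample_b_frequencies(config, rng)
    if config.ld_block > 1:
        # copy each block's leading frequency so duplicated columns share p
        lead = (np.arange(config.n_markers) // config.ld_block) * config.ld_block
        p = p[lead]
    # dosage = sum of two Bernoulli(p) allele draws
    draws = rng.random((len(names), config.n_markers, 2)) < p[None, :, None]
    dosages = draws.sum(axis=2).astype(np.int8)
    if config.ld_block > 1:
        dosages = dosages[:, lead]  # perfect LD within each founder block
    markers = _marker_table(config.n_markers)
    return GenotypePanel(names, markers, dosages), p


def gene_drop(
    founder_panel: GenotypePanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypePanel, TruePedigree]:
    """Mendelian transmission through the configured pedigree events.

    Each child receives, independently per marker, one uniformly chosen
    allele from each parent; a selfing draws both gametes from the same
    parent; clones copy dosages exactly (pre-error).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31))
    geno: dict[str, np.ndarray] = {
        s: founder_panel.dosages[i].copy() for i, s in enumerate(founder_panel.samples)
    }
    parents: dict[str, tuple[str, str]] = {}
    clones: dict[str, str] = {}

    def gamete(d: np.ndarray) -> np.ndarray:
        # transmit B with probability dosage/2
        return (rng.random(d.shape) < d / 2.0).astype(np.int8)

    for ev in config.events:
        if isinstance(ev, Cross):
            if ev.parent1 not in geno or ev.parent2 not in geno:
                raise ValueError(f"cross references missing individual: {ev}")
            geno[ev.child] = gamete(geno[ev.parent1]) + gamete(geno[ev.parent2])
            parents[ev.child] = (ev.parent1, ev.parent2)
        elif isinstance(ev, Self):
            if ev.parent not in geno:
                raise ValueError(f"selfing references missing individual: {ev}")
            geno[ev.child] = gamete(geno[ev.parent]) + gamete(geno[ev.parent])
            parents[ev.child] = (ev.parent, ev.parent)
        else:
            if ev.source not in geno:
                raise ValueError(f"clone references missing individual: {ev}")
            geno[ev.copy] = geno[ev.source].copy()
            clones[ev.copy] = ev.source
    names = list(geno)
    panel = GenotypePanel(
        names, founder_panel.markers.copy(), np.vstack([geno[n] for n in names])
    )
    truth = TruePedigree(parents, clones, list(founder_panel.samples), config.hidden)
    return panel, truth


def corrupt(
    panel: GenotypePanel,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator | int,
) -> GenotypePanel:
    """Symmetric genotyping error then random missingness.

    Each non-missing call is independently replaced, with probability
    ``error_rate``, by one of the other two dosage values uniformly; then
    each call is set to missing with probability ``missing_rate``.
    """
    if not (0 <= error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = panel.copy()
    d = out.dosages
    called = d != MISSING
    if error_rate > 0:
        err = called & (rng.random(d.shape) < error_rate)
        # add 1 or 2 mod 3 -> one of the other two values, uniformly
        shift = rng.integers(1, 3, size=int(err.sum()), dtype=np.int8)
        d[err] = (d[err] + shift) % 3
    if missing_rate > 0:
        drop = rng.random(d.shape) < missing_rate
        d[drop] = MISSING
    return out


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypePanel, TruePedigree, np.ndarray]:
    """Founders + gene drop + corruption; hidden individuals removed.

    Returns (released panel, truth, true B frequencies).  All randomness
    derives from ``config.seed``.
    """
    master = np.random.default_rng(config.seed)
    seeds = master.integers(2**31, size=3)
    founders, p = simulate_founders(config, np.random.default_rng(seeds[0]))
    full, truth = gene_drop(founders, config, np.random.default_rng(seeds[1]))
    noisy = corrupt(
        full, config.genotype_error_rate, config.missing_rate,
        np.random.default_rng(seeds[2]),
    )
    released = noisy.subset_samples([s for s in noisy.samples if s not in config.hidden])
    return released, truth, p


def calibration_experiment(
    seed: int, n_pairs: int = 50, n_markers: int = 2000
) -> tuple[GenotypePanel, np.ndarray, dict[str, list[tuple[str, str]]]]:
    """Independent pair replicates for estimator calibration.

    Simulates ``n_pairs`` disjoint pairs for each relationship class —
    parent-offspring, full sibs, half sibs, unrelated — over unlinked
    markers, error-free.  Returns (panel, true B frequencies, pairs by
    class).  Expected (k0, k1, k2): PO (0, 1, 0), FS (1/4, 1/2, 1/4),
    HS (1/2, 1/2, 0), UNREL (1, 0, 0).
    """
    events: list[Event] = []
    pairs: dict[str, list[tuple[str, str]]] = {"PO": [], "FS": [], "HS": [], "UNREL": []}
    f = iter(range(1, 10_000))

    def founder() -> str:
        return f"F{next(f):04d}"

    n_founders = 0
    for i in range(n_pairs):
        a, b = founder(), founder()
        pairs["UNREL"].append((a, b))
        pa, pb = founder(), founder()
        events.append(Cross(pa, pb, f"PO{i}"))
        pairs["PO"].append((f"PO{i}", pa))
        fa, fb = founder(), founder()
        events.append(Cross(fa, fb, f"FSa{i}"))
        events.append(Cross(fa, fb, f"FSb{i}"))
        pairs["FS"].append((f"FSa{i}", f"FSb{i}"))
        ha, hb, hc = founder(), founder(), founder()
        events.append(Cross(ha, hb, f"HSa{i}"))
        events.append(Cross(ha, hc, f"HSb{i}"))
        pairs["HS"].append((f"HSa{i}", f"HSb{i}"))
        n_founders += 9
    cfg = SimulationConfig(
        n_markers=n_markers, n_founders=n_founders, events=events,
        genotype_error_rate=0.0, missing_rate=0.0, seed=seed,
        founder_prefix="F",
    )
    # founder names above use a 4-digit pattern; align the config to it
    cfg.extra_founders = []
    names = [f"F{i + 1:04d}" for i in range(n_founders)]
    panel, truth, p = _simulate_named(cfg, names)
    return panel, p, pairs


def _simulate_named(
    cfg: SimulationConfig, founder_names: list[str]
) -> tuple[GenotypePanel, TruePedigree, np.ndarray]:
    """simulate_panel with an explicit founder-name list."""
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(2**31, size=3)
    rng = np.random.default_rng(seeds[0])
    p = sample_b_frequencies(cfg, rng)
    draws = rng.random((len(founder_names), cfg.n_markers, 2)) < p[None, :, None]
    founders = GenotypePanel(
        founder_names, _marker_table(cfg.n_markers), draws.sum(axis=2).astype(np.int8)
    )
    full, truth = gene_drop(founders, cfg, np.random.default_rng(seeds[1]))
    noisy = corrupt(
        full, cfg.genotype_error_rate, cfg.missing_rate, np.random.default_rng(seeds[2])
    )
    return noisy, truth, p


# -- the standard scenario ---------------------------------------------------


@dataclass
class Scenario:
    """A released panel plus everything a test needs to score recovery."""

    panel: GenotypePanel          # corrupted, hidden individuals removed
    truth: TruePedigree
    config: SimulationConfig
    clean_full: GenotypePanel     # error-free panel including hidden individuals
    freqs: np.ndarray             # true simulation B-allele frequencies


def standard_scenario_config(
    seed: int,
    n_markers: int = 6800,
    genotype_error_rate: float = 1e-4,
    missing_rate: float = 0.005,
) -> SimulationConfig:
    """Three-generation fixture with clones, selfing, trios, full sibs, two
    half-sib clusters through non-genotyped parents (one with genotyped
    grandparents and an avuncular relative), and unrelated singletons.

    Hidden individuals: MP1 (missing parent, child of F01 x F02, so F01/F02
    are a recoverable grandparent pair), MP2 (a second missing parent, child
    of F31 x F32), HF1/HF2 (hidden founders giving VIS and its full sib AVG
    a parental lineage), and HM1-3 (hidden unrelated mates of VIS).
    """
    ev: list[Event] = []
    # hidden missing parents and their genotyped relatives
    ev.append(Cross("F01", "F02", "MP1"))          # hidden
    ev.append(Cross("F01", "F02", "AVU"))          # genotyped FS of MP1 -> avuncular
    ev += [Cross(f"F{i:02d}", "MP1", f"HSA{k}") for k, i in enumerate((3, 4, 5, 6), 1)]
    ev.append(Cross("F31", "F32", "MP2"))          # hidden
    ev += [Cross(f"F{i:02d}", "MP2", f"HSB{k}") for k, i in enumerate((33, 34), 1)]
    # trios and a full-sib pair among them
    ev.append(Cross("F07", "F08", "T1"))
    ev.append(Cross("F07", "F08", "T2"))           # FS of T1
    ev.append(Cross("F09", "F10", "T3"))
    ev.append(Cross("F11", "F12", "T4"))
    ev.append(Cross("T1", "F13", "U1"))            # third generation
    ev.append(Cross("T3", "T4", "U2"))
    ev.append(Cross("F09", "F19", "X1"))           # half sib of T3 (shares F09)
    # selfing
    ev.append(Self("F14", "S1"))
    # founder-like parent with hidden parents, a genotyped full sib and
    # children through hidden mates (exercises the FS direction rule)
    ev.append(Cross("HF1", "HF2", "VIS"))
    ev.append(Cross("HF1", "HF2", "AVG"))
    ev.append(Cross("VIS", "HM1", "W1"))
    ev.append(Cross("VIS", "HM2", "W2"))
    ev.append(Cross("VIS", "HM3", "W3"))
    # extra two-generation trio families among spare founders
    ev.append(Cross("F21", "F22", "K1"))
    ev.append(Cross("F23", "F24", "K2"))
    ev.append(Cross("F25", "F26", "K3"))
    ev.append(Cross("F27", "F28", "K4"))
    ev.append(Cross("F29", "F30", "K5"))
    # clones
    ev.append(Clone("F01", "F01_clone"))
    ev.append(Clone("T1", "T1_clone"))
    ev.append(Clone("HSA1", "HSA1_clone"))
    ev.append(Clone("F20", "F20_clone"))
    # HF1/HF2 give VIS and AVG a shared hidden parental lineage; HM1-3 are
    # hidden unrelated mates; MP1/MP2 are the missing parents themselves.
    hidden = {"MP1", "MP2", "HF1", "HF2", "HM1", "HM2", "HM3"}
    return SimulationConfig(
        n_markers=n_markers,
        n_founders=45,  # F35..F45 stay unrelated singletons
        events=ev,
        genotype_error_rate=genotype_error_rate,
        missing_rate=missing_rate,
        seed=seed,
        hidden=hidden,
        extra_founders=["HF1", "HF2", "HM1", "HM2", "HM3"],
    )


def standard_scenario(
    seed: int,
    n_markers: int = 6800,
    genotype_error_rate: float = 1e-4,
    missing_rate: float = 0.005,
) -> Scenario:
    """Build the packaged multi-generation fixture (see
    :func:`standard_scenario_config`) and return panel + truth + clean copy."""
    cfg = standard_scenario_config(seed, n_markers, genotype_error_rate, missing_rate)
    master = np.random.default_rng(cfg.seed)
    seeds = master.integers(2**31, size=3)
    founders, p = simulate_founders(cfg, np.random.default_rng(seeds[0]))
    clean_full, truth = gene_drop(founders, cfg, np.random.default_rng(seeds[1]))
    noisy = corrupt(
        clean_full, cfg.genotype_error_rate, cfg.missing_rate,
        np.random.default_rng(seeds[2]),
    )
    released = noisy.subset_samples([s for s in noisy.samples if s not in cfg.hidden])
    return Scenario(released, truth, cfg, clean_full, p)
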
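"""Pairwise relatedness: IBS counting, method-of-moments IBD and Mendelian
errors.

The estimator inverts observed identity-by-state (IBS) counts into
identity-by-descent (IBD) state probabilities (k0, k1, k2) using the
allele-frequency-dependent conditional expectations

    P(IBS0 | IBD0) = 2 p^2 q^2
    P(IBS1 | IBD0) = 4 p^3 q + 4 p q^3
    P(IBS2 | IBD0) = p^4 + q^4 + 4 p^2 q^2
    P(IBS1 | IBD1) = 2 p q
    P(IBS2 | IBD1) = 1 - 2 p q
    P(IBS2 | IBD2) = 1

with p the B-allele frequency and q = 1 - p, summed over the pair's valid
(pairwise-complete, polymorphic) markers.  Solving in order,

    k0 = N0 / E[IBS0|IBD0]
    k1 = (N1 - k0 E[IBS1|IBD0]) / E[IBS1|IBD1]
    k2 = (N2 - k0 E[IBS2|IBD0] - k1 E[IBS2|IBD1]) / n_valid

then truncating each to [0, 1] and renormalizing to sum 1.  Kinship is
phi = k1/4 + k2/2.  Expected (k0, k1, k2): parent-offspring (0, 1, 0), full
sibs (1/4, 1/2, 1/4), second degree (1/2, 1/2, 0), unrelated (1, 0, 0).

Mendelian errors are genotype configurations impossible under Mendelian
transmission: for a duo, opposite homozygotes; for a trio, an offspring
genotype that cannot be assembled from one allele per parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel
from .qc import allele_frequencies


@dataclass(frozen=True)
class IBSCounts:
    """Marker counts at IBS state 0/1/2 for a pair of individuals."""

    id1: str
    id2: str
    n0: int
    n1: int
    n2: int

    @property
    def n_valid(self) -> int:
        return self.n0 + self.n1 + self.n2


@dataclass(frozen=True)
class ExpectedIBS:
    """Expected IBS-state counts conditional on IBD state, summed over markers.

    ``e_ij`` is E[count of IBS state i | IBD state j].  States that are
    impossible (IBS0 under IBD>=1, IBS1 under IBD2) are identically zero;
    E[IBS2 | IBD2] = n_valid.
    """

    e00: float
    e10: float
    e20: float
    e11: float
    e21: float
    n_valid: int
    n_excluded: int = 0  # monomorphic markers dropped


@dataclass(frozen=True)
class IBDEstimate:
    id1: str
    id2: str
    k0: float
    k1: float
    k2: float
    n_valid: int

    @property
    def kinship(self) -> float:
        return self.k1 / 4.0 + self.k2 / 2.0


@dataclass(frozen=True)
class DuoResult:
    id1: str
    id2: str
    mendelian_errors: int
    n_valid: int

    @property
    def error_rate(self) -> float:
        return self.mendelian_errors / self.n_valid if self.n_valid else float("nan")


@dataclass(frozen=True)
class TrioResult:
    offspring: str
    parent1: str
    parent2: str
    mendelian_errors: int
    n_valid: int

    @property
    def error_rate(self) -> float:
        return self.mendelian_errors / self.n_valid if self.n_valid else float("nan")


# -- IBS ---------------------------------------------------------------------


def _ibs_values(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """IBS state per marker: 2 - |d1 - d2| (0,1,2 dosage coding)."""
    return 2 - np.abs(d1.astype(np.int16) - d2.astype(np.int16))


def ibs_counts(
    panel: GenotypePanel, id1: str, id2: str, marker_mask: np.ndarray | None = None
) -> IBSCounts:
    """IBS state counts over pairwise-complete markers for one pair."""
    d1 = panel.dosages[panel.sample_index(id1)]
    d2 = panel.dosages[panel.sample_index(id2)]
    valid = (d1 != MISSING) & (d2 != MISSING)
    if marker_mask is not None:
        valid &= marker_mask
    ibs = _ibs_values(d1[valid], d2[valid])
    return IBSCounts(
        id1, id2, int((ibs == 0).sum()), int((ibs == 1).sum()), int((ibs == 2).sum())
    )


def expected_ibs(p: np.ndarray) -> ExpectedIBS:
    """Expected IBS-state counts given IBD, from per-marker B frequencies.

    Markers with p in {0, 1} (or NaN) carry no IBS information under these
    closed forms and are excluded with a count.
    """
    p = np.asarray(p, dtype=np.float64)
    ok = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    n_excluded = int((~ok).sum())
    p = p[ok]
    q = 1.0 - p
    e00 = float((2 * p**2 * q**2).sum())
    e10 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e20 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    e11 = float((2 * p * q).sum())
    e21 = float((1 - 2 * p * q).sum())
    return ExpectedIBS(e00, e10, e20, e11, e21, int(ok.sum()), n_excluded)


def _solve_k(
    n0: float, n1: float, n2: float, exp: ExpectedIBS, n_valid: float,
    constrain: bool = True,
):
    """Method-of-moments solve, scalar or ndarray.

    With ``constrain`` the raw solution is truncated to [0, 1] per component
    and renormalized onto the simplex.  Note the constrained estimator is
    biased toward the interior at boundary-true parameters (an unrelated
    pair's mean k0 sits a few percent below 1 at a few thousand markers);
    the raw solution is the calibrated one.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        k0 = n0 / exp.e00
        k1 = (n1 - k0 * exp.e10) / exp.e11
        k2 = (n2 - k0 * exp.e20 - k1 * exp.e21) / n_valid
    if not constrain:
        return k0, k1, k2
    k0 = np.clip(k0, 0.0, 1.0)
    k1 = np.clip(k1, 0.0, 1.0)
    k2 = np.clip(k2, 0.0, 1.0)
    total = k0 + k1 + k2
    return k0 / total, k1 / total, k2 / total


def mom_ibd(
    counts: IBSCounts, expected: ExpectedIBS, constrain: bool = True
) -> IBDEstimate:
    """PLINK-style method-of-moments (k0, k1, k2) for one pair.

    ``expected`` must be computed over the same marker set as ``counts``.
    ``constrain=False`` returns the raw (possibly out-of-simplex) moments
    solution, the unconstrained default of the reference implementations;
    the constrained form guarantees the simplex at the price of boundary
    bias.
    """
    if counts.n_valid == 0:
        raise ValueError(f"pair ({counts.id1}, {counts.id2}): no valid markers")
    if expected.e00 <= 0.0:
        raise ValueError("all markers near-monomorphic: E[IBS0|IBD0] = 0")
    k0, k1, k2 = _solve_k(
        counts.n0, counts.n1, counts.n2, expected, counts.n_valid, constrain
    )
    return IBDEstimate(counts.id1, counts.id2, float(k0), float(k1), float(k2), counts.n_valid)


# -- Mendelian errors --------------------------------------------------------


def mendel_errors_duo(
    panel: GenotypePanel, id1: str, id2: str, marker_mask: np.ndarray | None = None
) -> DuoResult:
    """Opposite-homozygote count over pairwise-complete markers."""
    d1 = panel.dosages[panel.sample_index(id1)]
    d2 = panel.dosages[panel.sample_index(id2)]
    valid = (d1 != MISSING) & (d2 != MISSING)
    if marker_mask is not None:
        valid &= marker_mask
    errors = int((np.abs(d1.astype(np.int16) - d2.astype(np.int16)) == 2)[valid].sum())
    return DuoResult(id1, id2, errors, int(valid.sum()))


def _trio_error_mask(off: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Markers where the offspring cannot receive one allele from each parent.

    Offspring 0 (AA) needs an A from both parents -> error if either parent
    is BB; offspring 2 symmetric; offspring 1 (AB) needs an A from one and a
    B from the other -> error if both parents AA or both BB.
    """
    return (
        ((off == 0) & ((p1 == 2) | (p2 == 2)))
        | ((off == 2) & ((p1 == 0) | (p2 == 0)))
        | ((off == 1) & (((p1 == 0) & (p2 == 0)) | ((p1 == 2) & (p2 == 2))))
    )


def mendel_errors_trio(
    panel: GenotypePanel,
    offspring: str,
    parent1: str,
    parent2: str,
    marker_mask: np.ndarray | None = None,
) -> TrioResult:
    """Trio Mendelian-error count over markers where all three are called."""
    if len({offspring, parent1, parent2}) != 3:
        raise ValueError("offspring and parents must be three distinct individuals")
    off = panel.dosages[panel.sample_index(offspring)]
    p1 = panel.dosages[panel.sample_index(parent1)]
    p2 = panel.dosages[panel.sample_index(parent2)]
    valid = (off != MISSING) & (p1 != MISSING) & (p2 != MISSING)
    if marker_mask is not None:
        valid &= marker_mask
    errors = int(_trio_error_mask(off, p1, p2)[valid].sum())
    return TrioResult(offspring, parent1, parent2, errors, int(valid.sum()))


# -- all-pairs tables --------------------------------------------------------


def pairwise_ibd(
    panel: GenotypePanel,
    freqs: np.ndarray | None = None,
    include_duo_errors: bool = True,
) -> pd.DataFrame:
    """Method-of-moments IBD (and duo Mendelian errors) for every pair.

    Frequencies default to those of ``panel`` itself; pass frequencies from
    a deduplicated panel when clones would bias p.  Monomorphic markers are
    excluded throughout.  Per-pair expectations honour each pair's own
    missingness pattern.

    Returns a tidy frame: id1, id2, n_valid, n0, n1, n2, k0, k1, k2,
    kinship [, duo_errors, duo_error_rate].
    """
    if freqs is None:
        freqs = allele_frequencies(panel)
    freqs = np.asarray(freqs, dtype=np.float64)
    poly = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)

    d = panel.dosages[:, poly]
    p = freqs[poly]
    q = 1.0 - p
    called = (d != MISSING)
    # one-hot dosage indicators (missing rows are all-zero)
    g = [(d == v).astype(np.float64) for v in (0, 1, 2)]
    cf = called.astype(np.float64)

    # observed IBS counts for all pairs
    n2 = g[0] @ g[0].T + g[1] @ g[1].T + g[2] @ g[2].T
    n0 = g[0] @ g[2].T + g[2] @ g[0].T
    n_valid = cf @ cf.T
    n1 = n_valid - n0 - n2

    # per-pair expectation sums over the pair's valid markers
    e00v = (2 * p**2 * q**2).astype(np.float64)
    e10v = (4 * p**3 * q + 4 * p * q**3).astype(np.float64)
    e20v = (p**4 + q**4 + 4 * p**2 * q**2).astype(np.float64)
    e11v = (2 * p * q).astype(np.float64)
    e21v = (1 - 2 * p * q).astype(np.float64)
    sums = {}
    for name, vec in (("e00", e00v), ("e10", e10v), ("e20", e20v),
                      ("e11", e11v), ("e21", e21v)):
        sums[name] = (cf * vec) @ cf.T

    with np.errstate(invalid="ignore", divide="ignore"):
        k0 = n0 / sums["e00"]
        k1 = (n1 - k0 * sums["e10"]) / sums["e11"]
        k2 = (n2 - k0 * sums["e20"] - k1 * sums["e21"]) / n_valid
    k0 = np.clip(k0, 0.0, 1.0)
    k1 = np.clip(k1, 0.0, 1.0)
    k2 = np.clip(k2, 0.0, 1.0)
    total = k0 + k1 + k2
    k0, k1, k2 = k0 / total, k1 / total, k2 / total

    if include_duo_errors:
        duo = g[0] @ g[2].T + g[2] @ g[0].T  # == n0 on the polymorphic set

    iu = np.triu_indices(panel.n_samples, k=1)
    samples = np.asarray(panel.samples)
    out = pd.DataFrame(
        {
            "id1": samples[iu[0]],
            "id2": samples[iu[1]],
            "n_valid": n_valid[iu].astype(np.int64),
            "n0": n0[iu].astype(np.int64),
            "n1": np.rint(n1[iu]).astype(np.int64),
            "n2": n2[iu].astype(np.int64),
            "k0": k0[iu].astype(np.float64),
            "k1": k1[iu].astype(np.float64),
            "k2": k2[iu].astype(np.float64),
        }
    )
    out["kinship"] = out["k1"] / 4.0 + out["k2"] / 2.0
    if include_duo_errors:
        out["duo_errors"] = duo[iu].astype(np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["duo_error_rate"] = out["duo_errors"] / out["n_valid"]
    return out


def pairwise_duo_errors(panel: GenotypePanel) -> pd.DataFrame:
    """Opposite-homozygote counts for all pairs, over all called markers."""
    d = panel.dosages
    g0 = (d == 0).astype(np.float64)
    g2 = (d == 2).astype(np.float64)
    cf = panel.called().astype(np.float64)
    errors = g0 @ g2.T + g2 @ g0.T
    n_valid = cf @ cf.T
    iu = np.triu_indices(panel.n_samples, k=1)
    samples = np.asarray(panel.samples)
    out = pd.DataFrame(
        {
            "id1": samples[iu[0]],
            "id2": samples[iu[1]],
            "n_valid": n_valid[iu].astype(np.int64),
            "duo_errors": errors[iu].astype(np.int64),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out["duo_error_rate"] = out["duo_errors"] / out["n_valid"]
    return out
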
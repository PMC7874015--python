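"""Independent brute-force oracles for the relatedness estimator.

Everything here is computed by exhaustive enumeration of ordered genotype or
allele configurations — no closed forms shared with the implementation — so
it can serve as an independent cross-check of the method-of-moments path.
"""

from __future__ import annotations

import numpy as np

# IBS lookup over ordered dosage pairs (0,1,2)
_IBS = {
    (0, 0): 2, (1, 1): 2, (2, 2): 2,
    (0, 1): 1, (1, 0): 1, (1, 2): 1, (2, 1): 1,
    (0, 2): 0, (2, 0): 0,
}


def _genotype_probs(p: float) -> dict[int, float]:
    """HWE genotype probabilities by B-dosage (enumerating allele draws)."""
    probs = {0: 0.0, 1: 0.0, 2: 0.0}
    for a1 in (0, 1):
        for a2 in (0, 1):
            pr = (p if a1 else 1 - p) * (p if a2 else 1 - p)
            probs[a1 + a2] += pr
    return probs


def ibs_given_ibd(p: float) -> np.ndarray:
    """P(IBS = i | IBD = z) for one marker, by enumeration.

    Returns a 3x3 array indexed [ibs_state, ibd_state].
    """
    out = np.zeros((3, 3))
    g = _genotype_probs(p)
    # IBD 0: two independent HWE genotypes
    for g1, p1 in g.items():
        for g2, p2 in g.items():
            out[_IBS[g1, g2], 0] += p1 * p2
    # IBD 1: one shared allele + one free allele each
    for shared in (0, 1):
        ps = p if shared else 1 - p
        for x in (0, 1):
            px = p if x else 1 - p
            for y in (0, 1):
                py = p if y else 1 - p
                out[_IBS[shared + x, shared + y], 1] += ps * px * py
    # IBD 2: both genotypes identical
    for g1, p1 in g.items():
        out[_IBS[g1, g1], 2] += p1
    return out


def expected_counts(freqs: np.ndarray) -> np.ndarray:
    """Sum of per-marker conditional IBS tables over markers (3x3)."""
    total = np.zeros((3, 3))
    for p in freqs:
        total += ibs_given_ibd(float(p))
    return total


def solve_mom(n0: float, n1: float, n2: float, e: np.ndarray) -> tuple[float, float, float]:
    """Scalar re-derivation of the moments inversion from the 3x3 expected
    table; truncates to [0, 1] and renormalizes."""
    n_valid = n0 + n1 + n2
    k0 = n0 / e[0, 0]
    k1 = (n1 - k0 * e[1, 0]) / e[1, 1]
    k2 = (n2 - k0 * e[2, 0] - k1 * e[2, 1]) / n_valid
    ks = [min(1.0, max(0.0, k)) for k in (k0, k1, k2)]
    s = sum(ks)
    return ks[0] / s, ks[1] / s, ks[2] / s


def ibs_counts_loop(d1: np.ndarray, d2: np.ndarray) -> tuple[int, int, int]:
    """Per-marker python loop IBS counting (missing = -1 skipped)."""
    n = [0, 0, 0]
    for a, b in zip(d1.tolist(), d2.tolist()):
        if a < 0 or b < 0:
            continue
        n[_IBS[a, b]] += 1
    return tuple(n)


def duo_errors_loop(d1: np.ndarray, d2: np.ndarray) -> int:
    """Opposite-homozygote counting by per-marker loop."""
    errs = 0
    for a, b in zip(d1.tolist(), d2.tolist()):
        if a < 0 or b < 0:
            continue
        if (a, b) in ((0, 2), (2, 0)):
            errs += 1
    return errs


def trio_errors_loop(off: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> int:
    """Trio errors by enumerating every gamete pair per marker."""
    alleles = {0: [0], 1: [0, 1], 2: [1]}
    errs = 0
    for o, a, b in zip(off.tolist(), p1.tolist(), p2.tolist()):
        if min(o, a, b) < 0:
            continue
        ok = any(o == x + y for x in alleles[a] for y in alleles[b])
        errs += not ok
    return errs
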
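"""Marker/individual QC, allele frequencies and LD pruning.

QC mirrors common array-genotyping practice for germplasm panels: markers are
dropped on missingness and minor-allele frequency; individuals are dropped on
missingness, with an optional heterozygosity window used before parentage
analysis (grossly aberrant heterozygosity flags sample quality problems or
inter-specific material).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

log = logging.getLogger(__name__)

#: (max individual missingness, heterozygosity window) presets
INDIVIDUAL_PRESETS: dict[str, tuple[float, tuple[float, float] | None]] = {
    "qc": (0.05, None),
    "parentage": (0.01, (0.25, 0.45)),
}


def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Per-marker B-allele frequency p_B = sum(dosage) / (2 * n called).

    Markers with zero non-missing calls get NaN.
    """
    called = panel.called()
    n_called = called.sum(axis=0)
    totals = np.where(called, panel.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = totals / (2.0 * n_called)
    p[n_called == 0] = np.nan
    return p


def marker_qc(panel: GenotypePanel) -> pd.DataFrame:
    """Per-marker call_rate, B-allele frequency and MAF."""
    called = panel.called()
    call_rate = called.mean(axis=0) if panel.n_samples else np.zeros(panel.n_markers)
    p = allele_frequencies(panel)
    maf = np.minimum(p, 1.0 - p)
    return pd.DataFrame(
        {"call_rate": call_rate, "p_b": p, "maf": maf}, index=panel.markers.index
    )


def individual_qc(panel: GenotypePanel) -> pd.DataFrame:
    """Per-individual missingness and heterozygosity.

    Heterozygosity is the fraction of non-missing calls equal to dosage 1;
    NaN (flagged) when all calls are missing.
    """
    called = panel.called()
    n_called = called.sum(axis=1)
    missingness = 1.0 - n_called / max(panel.n_markers, 1)
    het_calls = (panel.dosages == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = het_calls / n_called
    het[n_called == 0] = np.nan
    return pd.DataFrame(
        {"missingness": missingness, "heterozygosity": het}, index=panel.samples
    )


def filter_markers(
    panel: GenotypePanel, max_missing: float = 0.01, min_maf: float = 0.05
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop markers with missingness > max_missing or MAF < min_maf.

    Returns (filtered panel, report); the report lists each removed marker
    with its QC values and the removal reason.
    """
    stats = marker_qc(panel)
    missingness = 1.0 - stats["call_rate"]
    bad_miss = missingness > max_missing
    bad_maf = stats["maf"].fillna(-1.0) < min_maf
    reasons = []
    for mid in panel.markers.index:
        r = []
        if bad_miss.loc[mid]:
            r.append(f"missingness > {max_missing:g}")
        if bad_maf.loc[mid]:
            r.append(f"MAF < {min_maf:g}")
        reasons.append("; ".join(r))
    report = stats.assign(missingness=missingness, reason=reasons)
    report = report[report["reason"] != ""].copy()
    keep = [m for m in panel.markers.index if m not in set(report.index)]
    if not keep:
        log.warning("all markers removed by QC")
        out = panel.subset_markers([])
    else:
        out = panel.subset_markers(keep)
    return out, report


def filter_individuals(
    panel: GenotypePanel,
    max_missing: float | None = None,
    het_range: tuple[float, float] | None = None,
    preset: str | None = None,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop individuals on missingness and (optionally) heterozygosity.

    Either give thresholds directly or name a ``preset``: ``"qc"`` (5%
    missingness, no heterozygosity bound) or ``"parentage"`` (1% missingness,
    heterozygosity within [0.25, 0.45]).
    """
    if preset is not None:
        max_missing, het_range = INDIVIDUAL_PRESETS[preset]
    if max_missing is None:
        raise ValueError("max_missing required when no preset is given")
    stats = individual_qc(panel)
    bad_miss = stats["missingness"] > max_missing
    if het_range is not None:
        lo, hi = het_range
        het = stats["heterozygosity"]
        bad_het = het.isna() | (het < lo) | (het > hi)
    else:
        bad_het = pd.Series(False, index=stats.index)
    reasons = []
    for s in panel.samples:
        r = []
        if bad_miss.loc[s]:
            r.append(f"missingness > {max_missing:g}")
        if bad_het.loc[s]:
            r.append(f"heterozygosity outside [{het_range[0]:g}, {het_range[1]:g}]")
        reasons.append("; ".join(r))
    report = stats.assign(reason=reasons)
    report = report[report["reason"] != ""].copy()
    keep = [s for s in panel.samples if s not in set(report.index)]
    return panel.subset_samples(keep), report


# -- LD pruning --------------------------------------------------------------


def _pairwise_complete_r2(dosages: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns over pairwise-
    complete individuals (composite LD for unphased data).

    Pairs with < 2 shared calls or zero variance get r^2 = 0.
    """
    X = dosages.astype(np.float64)
    M = called.astype(np.float64)
    Z = X * M
    Z2 = (X * X) * M
    n = M.T @ M                      # shared call counts
    sx = Z.T @ M                     # sum of x over the joint mask
    sxy = Z.T @ Z
    sxx = Z2.T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n
        r2 = cov * cov / (varx * varx.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.8,
    window: int = 50,
    step: int = 5,
) -> tuple[GenotypePanel, list[str]]:
    """Greedy sliding-window LD pruning.

    Within each window of ``window`` markers (advancing by ``step``, never
    spanning chromosomes), every pair of retained markers with r^2 > r2_max
    drops the later marker by position.  Deterministic for fixed input.

    Returns (pruned panel, list of dropped marker ids).
    """
    panel = panel.sort_markers()
    keep = np.ones(panel.n_markers, dtype=bool)
    chroms = panel.markers["chrom"].to_numpy()
    called = panel.called()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step):
            win = idx[start : start + window]
            if len(win) < 2:
                continue
            sub = np.flatnonzero(keep[win])
            if len(sub) < 2:
                continue
            cols = win[sub]
            r2 = _pairwise_complete_r2(panel.dosages[:, cols], called[:, cols])
            local_keep = np.ones(len(cols), dtype=bool)
            for a in range(len(cols)):
                if not local_keep[a]:
                    continue
                for b in range(a + 1, len(cols)):
                    if local_keep[b] and r2[a, b] > r2_max:
                        local_keep[b] = False
            keep[cols[~local_keep]] = False
            if start + window >= len(idx):
                break
    kept_ids = [m for m, k in zip(panel.markers.index, keep) if k]
    dropped = [m for m, k in zip(panel.markers.index, keep) if not k]
    return panel.subset_markers(kept_ids), dropped
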
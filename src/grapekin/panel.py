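"""Genotype panel data model.

A :class:`GenotypePanel` holds diploid biallelic SNP genotypes as B-allele
dosages (0, 1, 2) in a dense individuals x markers matrix, with ``-1`` as the
missing sentinel.  Dosage 0 is a valid homozygote (AA), so missingness is
never encoded as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.  Reserved; never a valid dosage.
MISSING: int = -1

MARKER_COLUMNS = ["chrom", "pos", "allele_a", "allele_b"]


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel data."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP marker.

    ``allele_a`` is the reference-like allele (dosage counts copies of
    ``allele_b``); position is 1-based, VCF convention.
    """

    marker_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise PanelError(f"marker {self.marker_id}: alleles must differ")
        if self.pos < 1:
            raise PanelError(f"marker {self.marker_id}: position must be >= 1")


@dataclass
class GenotypePanel:
    """Individuals x markers dosage matrix with marker metadata.

    Parameters
    ----------
    samples
        Ordered unique sample names.
    markers
        DataFrame indexed by marker_id with columns ``chrom``, ``pos``,
        ``allele_a``, ``allele_b``.
    dosages
        int8 array of shape (n_samples, n_markers); values in {0, 1, 2}
        or :data:`MISSING`.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise PanelError(f"duplicate sample names: {dupes}")
        if not self.markers.index.is_unique:
            raise PanelError("duplicate marker ids")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise PanelError(f"marker table lacks columns {missing_cols}")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise PanelError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PanelError(f"{bad.sum()} dosage values outside {{0,1,2,{MISSING}}}")
        if (self.markers["allele_a"] == self.markers["allele_b"]).any():
            raise PanelError("marker with identical alleles")

    # -- basic introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in panel") from None

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, same shape as ``dosages``."""
        return self.dosages != MISSING

    # -- construction helpers ------------------------------------------------

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(list(self.samples), self.markers.copy(), self.dosages.copy())

    def subset_samples(self, names: list[str]) -> "GenotypePanel":
        idx = [self.sample_index(n) for n in names]
        return GenotypePanel(list(names), self.markers.copy(), self.dosages[idx].copy())

    def subset_markers(self, marker_ids: list[str]) -> "GenotypePanel":
        pos = pd.Index(self.markers.index).get_indexer(marker_ids)
        if (pos < 0).any():
            missing = [m for m, p in zip(marker_ids, pos) if p < 0]
            raise KeyError(f"markers not in panel: {missing[:5]}")
        return GenotypePanel(
            list(self.samples), self.markers.iloc[pos].copy(), self.dosages[:, pos].copy()
        )

    def sort_markers(self) -> "GenotypePanel":
        """Return a copy with markers sorted by (chrom, pos)."""
        order = self.markers.sort_values(["chrom", "pos"], kind="stable").index
        return self.subset_markers(list(order))

    def flip_markers(self, marker_ids: list[str]) -> "GenotypePanel":
        """Swap allele labels (A<->B) for the given markers; dosages d -> 2-d.

        Applying the same flip twice is the identity.
        """
        out = self.copy()
        pos = pd.Index(out.markers.index).get_indexer(marker_ids)
        if (pos < 0).any():
            raise KeyError("flip of marker not in panel")
        cols = out.dosages[:, pos]
        called = cols != MISSING
        cols[called] = 2 - cols[called]
        out.dosages[:, pos] = cols
        a = out.markers.iloc[pos]["allele_a"].copy()
        out.markers.iloc[pos, out.markers.columns.get_loc("allele_a")] = out.markers.iloc[
            pos
        ]["allele_b"].to_numpy()
        out.markers.iloc[pos, out.markers.columns.get_loc("allele_b")] = a.to_numpy()
        return out

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame (samples x marker_ids), MISSING as NaN."""
        df = pd.DataFrame(
            self.dosages.astype(float), index=self.samples, columns=self.markers.index
        )
        return df.where(df != MISSING, other=np.nan)

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.samples == other.samples
            and list(self.markers.index) == list(other.markers.index)
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
            and np.array_equal(self.dosages, other.dosages)
        )


def make_panel(
    samples: list[str],
    markers: list[Marker] | pd.DataFrame,
    dosages: np.ndarray,
) -> GenotypePanel:
    """Build a panel from a list of :class:`Marker` (or a ready marker table)."""
    if isinstance(markers, pd.DataFrame):
        table = markers
    else:
        table = pd.DataFrame(
            {
                "chrom": [m.chrom for m in markers],
                "pos": [m.pos for m in markers],
                "allele_a": [m.allele_a for m in markers],
                "allele_b": [m.allele_b for m in markers],
            },
            index=pd.Index([m.marker_id for m in markers], name="marker_id"),
        )
    return GenotypePanel(samples, table, np.asarray(dosages, dtype=np.int8))
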
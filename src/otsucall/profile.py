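"""Binned read-depth profiles.

The fundamental signal of an RD-based CNV caller: one mean read depth per
fixed-width genomic bin. Bins overlapping unassembled reference sequence
(N runs) are removed, but the boolean mask over the *original* bin grid is
kept so every retained bin can be mapped back to genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RDProfile"]


@dataclass
class RDProfile:
    """Per-chromosome binned read-depth vector.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    bin_size : int
        Width of each bin in bases.
    values : ndarray of float
        Read depth of each *retained* (unmasked) bin, in original order.
    mask : ndarray of bool, optional
        One flag per bin of the original grid; ``True`` marks a bin that was
        removed (e.g. because it overlaps N bases). Defaults to all-``False``
        with the same length as ``values``.

    Notes
    -----
    Coordinates are 0-based half-open internally; emitted files use 1-based
    inclusive positions.
    """

    chrom: str
    bin_size: int
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size and self.values.min() < 0:
            raise ValueError("read-depth values must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.values.size, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if int((~self.mask).sum()) != self.values.size:
            raise ValueError(
                "mask/values mismatch: "
                f"{int((~self.mask).sum())} unmasked bins vs {self.values.size} values"
            )

    # -- sizes ---------------------------------------------------------------
    @property
    def n_bins(self) -> int:
        """Number of retained bins (length of ``values``)."""
        return self.values.size

    @property
    def n_bins_total(self) -> int:
        """Number of bins on the original grid, masked bins included."""
        return self.mask.size

    # -- coordinates ---------------------------------------------------------
    def retained_bins(self) -> np.ndarray:
        """Original-grid bin indices of the retained bins."""
        return np.flatnonzero(~self.mask)

    def bin_start(self, i: int) -> int:
        """0-based genomic start of retained bin ``i``."""
        return int(self.retained_bins()[i]) * self.bin_size

    def bin_starts(self) -> np.ndarray:
        """0-based genomic starts of all retained bins."""
        return self.retained_bins() * self.bin_size

    def with_values(self, values: np.ndarray) -> "RDProfile":
        """Copy of this profile with ``values`` replaced (same mask)."""
        return RDProfile(self.chrom, self.bin_size, np.asarray(values, float), self.mask.copy())
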
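"""Sliding-window grids and profiles shared by the BSA and sweep scans.

Windows are anchored at position 1 and advance by ``step``; each window is
the half-open base-pair interval ``[start, start + width)``.  The last,
possibly partial, windows are kept.  A window with no contributing markers
carries a missing value (NaN), never 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridMismatchError(ValueError):
    """Two window profiles do not share the same window grid."""


def window_starts(chrom_length: int, width: int, step: int) -> np.ndarray:
    """1-based window start positions tiling ``[1, chrom_length]``."""
    if chrom_length < 1 or width < 1 or step < 1:
        raise ValueError("chrom_length, width and step must be positive")
    return np.arange(1, chrom_length + 1, step, dtype=np.int64)


@dataclass
class WindowProfile:
    """A per-window statistic along one chromosome.

    ``values`` holds the windowed statistic (NaN = missing) and
    ``n_markers`` the number of sites that contributed to each window.
    ``raw_values`` optionally retains the statistic before any clamping.
    """

    chrom: str
    starts: np.ndarray
    width: int
    step: int
    values: np.ndarray
    n_markers: np.ndarray
    raw_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        self.n_markers = np.asarray(self.n_markers, dtype=np.int64)
        if not (len(self.starts) == len(self.values) == len(self.n_markers)):
            raise ValueError("starts, values and n_markers must align")

    @property
    def ends(self) -> np.ndarray:
        """Half-open window end positions (``start + width``)."""
        return self.starts + self.width

    def same_grid(self, other: "WindowProfile") -> bool:
        return (
            self.chrom == other.chrom
            and self.width == other.width
            and self.step == other.step
            and len(self.starts) == len(other.starts)
            and bool(np.array_equal(self.starts, other.starts))
        )

    def require_grid(self, other: "WindowProfile") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                "window grids differ (chrom/width/step/starts)"
            )

    def to_frame(self):
        """BED-like table: chrom, 0-based start, end, value, n_markers."""
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start0": self.starts - 1,
                "end": self.starts - 1 + self.width,
                "value": self.values,
                "n_markers": self.n_markers,
            }
        )


def window_aggregate(
    positions: np.ndarray,
    values: np.ndarray,
    starts: np.ndarray,
    width: int,
    how: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate per-site values into windows ``[start, start + width)``.

    ``positions`` must be sorted 1-based site positions; ``values`` is a
    matching vector, or a 2-D array whose *last* axis aligns with sites
    (used to window many permutation replicates at once).  NaN values are
    ignored; windows with no non-NaN site are NaN.  Returns
    ``(aggregated, n_sites)`` where ``n_sites`` counts non-NaN sites.
    """
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != len(positions):
        raise ValueError("values last axis must align with positions")
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, starts + width, side="left")

    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    pad = [(0, 0)] * (values.ndim - 1) + [(1, 0)]
    csum = np.pad(np.cumsum(filled, axis=-1), pad)
    ccnt = np.pad(np.cumsum(finite, axis=-1), pad)

    sums = csum[..., hi] - csum[..., lo]
    counts = ccnt[..., hi] - ccnt[..., lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        if how == "mean":
            out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        elif how == "sum":
            out = np.where(counts > 0, sums, np.nan)
        else:
            raise ValueError(f"unknown aggregation {how!r}")
    return out, counts
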
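"""SNP/InDel-index scanning for bulked-segregant trait mapping.

For each informative marker, the index of a bulk is the fraction of reads
supporting the non-reference (non-P50) allele: 0 means the bulk looks like
the recessive P50 parent, 1 means it is fixed for the wild allele.  The
ΔSNP/InDel index is the difference of windowed indexes between the
trait-positive and trait-negative bulks.  In an ideal BC1 dominant design
the trait-positive bulk is heterozygous at the causal locus (index 0.5)
and the trait-negative bulk is homozygous P50 (index 0), so Δ → 0.5 at
the causal locus and 0 elsewhere.

Confidence bands for Δ come from resampling bulk read counts at the
observed depths under the no-linkage null: a random BC1 bulk is half
heterozygotes, so the expected non-reference read fraction is 0.25 in
both bulks.  Per-window empirical quantiles over the replicates give the
band at the requested confidence level.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .variant_io import MarkerTable
from .windows import GridMismatchError, WindowProfile, window_aggregate, window_starts

__all__ = [
    "snp_index",
    "window_profile",
    "delta_profile",
    "permutation_band",
    "exceedance",
    "candidate_regions",
    "intersect_regions",
    "ThresholdBand",
    "CandidateRegion",
]


def snp_index(ref_count, nonref_count):
    """Per-site index: non-reference reads / total reads (NaN at depth 0)."""
    ref = np.asarray(ref_count, dtype=float)
    nonref = np.asarray(nonref_count, dtype=float)
    depth = ref + nonref
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(depth > 0, nonref / np.where(depth > 0, depth, 1), np.nan)
    if idx.ndim == 0:
        return float(idx)
    return idx


def _single_chrom(markers: MarkerTable) -> str:
    chroms = markers.chroms()
    if len(chroms) != 1:
        raise ValueError(
            f"profile functions operate on one chromosome at a time, got {chroms}"
        )
    return chroms[0]


def window_profile(
    markers: MarkerTable,
    bulk: str,
    width: int = 1_000_000,
    step: int = 10_000,
    chrom_length: int | None = None,
) -> WindowProfile:
    """Windowed mean index of one bulk over a 1-chromosome marker table.

    The window value is the unweighted mean of the per-marker indexes of
    all markers whose position falls in ``[start, start + width)``;
    windows without markers are missing.
    """
    chrom = _single_chrom(markers)
    pos = markers.positions()
    ref, nonref = markers.counts(bulk)
    idx = snp_index(ref, nonref)
    if chrom_length is None:
        chrom_length = int(pos[-1]) if len(pos) else width
    starts = window_starts(chrom_length, width, step)
    values, counts = window_aggregate(pos, np.atleast_1d(idx), starts, width, "mean")
    return WindowProfile(chrom, starts, width, step, values, counts)


def delta_profile(profile_pos: WindowProfile, profile_neg: WindowProfile) -> WindowProfile:
    """Δ profile: trait-positive windowed index minus trait-negative.

    Missing on either side propagates; grids must match exactly.
    """
    profile_pos.require_grid(profile_neg)
    values = profile_pos.values - profile_neg.values
    counts = np.minimum(profile_pos.n_markers, profile_neg.n_markers)
    return WindowProfile(
        profile_pos.chrom,
        profile_pos.starts,
        profile_pos.width,
        profile_pos.step,
        values,
        counts,
    )


@dataclass
class ThresholdBand:
    """Per-window Δ-index confidence band under the no-linkage null."""

    chrom: str
    starts: np.ndarray
    width: int
    step: int
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_perm: int
    null_freq: float
    description: str = "binomial resampling at observed depths"

    def same_grid(self, profile: WindowProfile) -> bool:
        return (
            self.chrom == profile.chrom
            and self.width == profile.width
            and self.step == profile.step
            and bool(np.array_equal(self.starts, profile.starts))
        )


def permutation_band(
    markers: MarkerTable,
    bulk_pos: str,
    bulk_neg: str,
    width: int = 1_000_000,
    step: int = 10_000,
    n_perm: int = 1000,
    level: float = 0.95,
    null_freq: float = 0.25,
    seed: int | None = None,
    chrom_length: int | None = None,
) -> ThresholdBand:
    """Δ-index confidence band from ``n_perm`` null replicates.

    Each replicate redraws every marker's two bulk non-reference counts
    as Binomial(observed depth, ``null_freq``) independently — the
    no-linkage expectation for a BC1 extreme-bulk design (a random bulk
    is half heterozygotes, hence an expected non-reference read fraction
    of 0.25).  The band is the per-window empirical (1−level)/2 and
    1−(1−level)/2 quantiles of the windowed Δ over replicates.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives unstable tail quantiles; use >= 100",
            stacklevel=2,
        )
    chrom = _single_chrom(markers)
    rng = np.random.default_rng(seed)
    pos = markers.positions()
    if chrom_length is None:
        chrom_length = int(pos[-1]) if len(pos) else width
    starts = window_starts(chrom_length, width, step)

    deltas = None
    for bulk, sign in ((bulk_pos, 1.0), (bulk_neg, -1.0)):
        ref, nonref = markers.counts(bulk)
        depth = (ref + nonref).astype(np.int64)
        draws = rng.binomial(depth[None, :], null_freq, size=(n_perm, len(depth)))
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(depth[None, :] > 0, draws / np.maximum(depth, 1), np.nan)
        win, _ = window_aggregate(pos, idx, starts, width, "mean")
        deltas = sign * win if deltas is None else deltas + sign * win

    alpha = (1.0 - level) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        lower = np.nanquantile(deltas, alpha, axis=0)
        upper = np.nanquantile(deltas, 1.0 - alpha, axis=0)
    return ThresholdBand(
        chrom=chrom,
        starts=starts,
        width=width,
        step=step,
        lower=lower,
        upper=upper,
        level=level,
        n_perm=n_perm,
        null_freq=null_freq,
    )


def exceedance(delta: WindowProfile, band: ThresholdBand, side: str = "both") -> np.ndarray:
    """Boolean mask of windows whose Δ falls outside the band.

    ``side``: "upper" (Δ > upper), "lower" (Δ < lower) or "both".
    Missing windows (in Δ or the band) are never flagged.
    """
    if not band.same_grid(delta):
        raise GridMismatchError("band grid does not match Δ profile grid")
    d = delta.values
    ok = np.isfinite(d) & np.isfinite(band.upper) & np.isfinite(band.lower)
    above = ok & (d > band.upper)
    below = ok & (d < band.lower)
    if side == "upper":
        return above
    if side == "lower":
        return below
    if side == "both":
        return above | below
    raise ValueError(f"unknown side {side!r}")


@dataclass
class CandidateRegion:
    """A contiguous run of outstanding Δ-index windows."""

    chrom: str
    start: int  # 1-based
    end: int  # half-open
    peak_delta: float
    n_windows: int
    label: str = ""

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def intersect(self, other: "CandidateRegion") -> "CandidateRegion | None":
        if self.chrom != other.chrom:
            return None
        start, end = max(self.start, other.start), min(self.end, other.end)
        if end <= start:
            return None
        return CandidateRegion(
            chrom=self.chrom,
            start=start,
            end=end,
            peak_delta=max(self.peak_delta, other.peak_delta),
            n_windows=min(self.n_windows, other.n_windows),
            label="&".join(x for x in (self.label, other.label) if x),
        )


def _merge_flagged(
    delta: WindowProfile, flagged: np.ndarray, label: str
) -> list[CandidateRegion]:
    regions: list[CandidateRegion] = []
    starts = delta.starts[flagged]
    vals = delta.values[flagged]
    if len(starts) == 0:
        return regions
    run_start = starts[0]
    run_end = starts[0] + delta.width
    peak = vals[0]
    n = 1
    for s, v in zip(starts[1:], vals[1:]):
        if s - run_end < delta.width:  # overlap or gap shorter than one window
            run_end = max(run_end, s + delta.width)
            peak = max(peak, v)
            n += 1
        else:
            regions.append(CandidateRegion(delta.chrom, int(run_start), int(run_end), float(peak), n, label))
            run_start, run_end, peak, n = s, s + delta.width, v, 1
    regions.append(CandidateRegion(delta.chrom, int(run_start), int(run_end), float(peak), n, label))
    return regions


def candidate_regions(
    delta: WindowProfile,
    band: ThresholdBand | None = None,
    mode: str = "strict",
    top_q: float = 0.005,
    side: str = "upper",
    label: str = "",
) -> list[CandidateRegion]:
    """Call candidate regions from a Δ profile.

    ``mode="strict"``: maximal runs of windows beyond the confidence band
    (``side`` selects the tail), merged when separated by less than one
    window width.  ``mode="peak"``: the top ``top_q`` fraction of windows
    ranked by Δ, merged the same way — the pragmatic call when no window
    clears the band but a peak is evident.  Ties in peak mode are broken
    by genomic order (leftmost first).
    """
    if mode == "strict":
        if band is None:
            raise ValueError("strict mode requires a ThresholdBand")
        flagged = exceedance(delta, band, side=side)
    elif mode == "peak":
        valid = np.flatnonzero(np.isfinite(delta.values))
        if len(valid) == 0:
            return []
        k = max(1, int(np.ceil(top_q * len(valid))))
        order = sorted(valid, key=lambda i: (-delta.values[i], delta.starts[i]))
        flagged = np.zeros(len(delta.values), dtype=bool)
        flagged[order[:k]] = True
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _merge_flagged(delta, flagged, label)


def intersect_regions(
    regions_a: list[CandidateRegion], regions_b: list[CandidateRegion]
) -> list[CandidateRegion]:
    """Interval intersection of two candidate-region sets (may be empty)."""
    out: list[CandidateRegion] = []
    for a in regions_a:
        for b in regions_b:
            hit = a.intersect(b)
            if hit is not None:
                out.append(hit)
    out.sort(key=lambda r: (r.chrom, r.start))
    return out
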
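"""Selective-sweep screening over two population panels.

A sweep leaves a local loss of diversity (π) in the selected population
and elevated differentiation (Fst) against an unselected population.
This module computes windowed Hudson-type Fst (ratio of averages, robust
to very unequal sample sizes such as a large domestic panel against a
handful of wild strains), windowed per-bp nucleotide diversity, and
per-site allele-frequency tracks, then flags windows in the top Fst
quantile whose domestic-panel diversity is below the wild-panel
diversity, reporting genes that overlap the flagged windows.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GeneModel
from .windows import WindowProfile, window_aggregate, window_starts

__all__ = [
    "PopulationPanel",
    "SweepCall",
    "allele_frequency",
    "allele_frequency_from_counts",
    "pi_window",
    "fst_window",
    "sweep_candidates",
    "allele_frequency_track",
]

MISSING_ALLELE = -1


@dataclass
class PopulationPanel:
    """Biallelic haploid genotype matrices for two labeled populations.

    Allele code 1 is the non-reference allele, 0 the reference allele,
    -1 missing.  ``pop1`` is conventionally the domestic panel and
    ``pop2`` the wild panel.  ``sweep_interval`` carries simulation truth
    when the panel was generated, for recovery tests.
    """

    chrom: str
    positions: np.ndarray  # 1-based, sorted
    pop1: np.ndarray  # (n_sites, n1) int8
    pop2: np.ndarray  # (n_sites, n2) int8
    chrom_length: int
    sweep_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.pop1 = np.asarray(self.pop1, dtype=np.int8)
        self.pop2 = np.asarray(self.pop2, dtype=np.int8)
        if self.pop1.shape[0] != len(self.positions) or self.pop2.shape[0] != len(
            self.positions
        ):
            raise ValueError("genotype matrices must have one row per site")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be sorted")

    @property
    def n1(self) -> int:
        return self.pop1.shape[1]

    @property
    def n2(self) -> int:
        return self.pop2.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Sites × haploid samples table of {0,1} (NA = missing)."""
        cols = {"pos": self.positions}
        for name, mat in (("dom", self.pop1), ("wild", self.pop2)):
            for j in range(mat.shape[1]):
                col = mat[:, j].astype(float)
                col[col == MISSING_ALLELE] = np.nan
                cols[f"{name}{j}"] = col
        return pd.DataFrame(cols)


def _site_freq(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site non-reference allele frequency and non-missing call count."""
    called = mat != MISSING_ALLELE
    n = called.sum(axis=1)
    alt = np.where(called, mat, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return p, n


def allele_frequency(panel: PopulationPanel, population: str = "pop1") -> np.ndarray:
    """Per-site reference-allele frequency (calls mode): ref calls / calls.

    Sites with no non-missing call are NaN.
    """
    mat = panel.pop1 if population in ("pop1", "dom") else panel.pop2
    p_alt, n = _site_freq(mat)
    return np.where(n > 0, 1.0 - p_alt, np.nan)


def allele_frequency_from_counts(ref_reads, total_reads):
    """Reference-allele frequency in read-count mode (NaN at zero depth)."""
    ref = np.asarray(ref_reads, dtype=float)
    tot = np.asarray(total_reads, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, ref / np.where(tot > 0, tot, 1), np.nan)
    return float(out) if out.ndim == 0 else out


def pi_window(
    panel: PopulationPanel,
    population: str = "pop1",
    width: int = 10_000,
    step: int = 5_000,
) -> WindowProfile:
    """Windowed per-bp nucleotide diversity π for one population.

    Per window, π = Σ_sites [2 p̂ (1−p̂) · n/(n−1)] / width, the unbiased
    per-site heterozygosity summed over contributing sites and divided by
    the window length in bp (not callable sites).  Sites with fewer than
    2 non-missing calls are skipped; windows with no contributing site
    are missing.
    """
    mat = panel.pop1 if population in ("pop1", "dom") else panel.pop2
    p, n = _site_freq(mat)
    usable = n >= 2
    with np.errstate(invalid="ignore"):
        h = np.where(usable, 2.0 * p * (1.0 - p) * n / np.maximum(n - 1, 1), np.nan)
    starts = window_starts(panel.chrom_length, width, step)
    sums, counts = window_aggregate(panel.positions, h, starts, width, "sum")
    values = sums / float(width)
    return WindowProfile(panel.chrom, starts, width, step, values, counts)


def _hudson_components(p1, n1, p2, n2):
    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / np.maximum(n1 - 1, 1)
        - p2 * (1.0 - p2) / np.maximum(n2 - 1, 1)
    )
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return num, den


def _wc_components(p1, n1, p2, n2):
    # Weir–Cockerham theta for haploid samples, two populations,
    # in mean-square form; windowed as ratio of averages.
    n_tot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / n_tot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / np.maximum(n_tot - 2, 1)
    nc = n_tot - (n1**2 + n2**2) / n_tot
    num = msp - msg
    den = msp + (nc - 1.0) * msg
    return num, den


def fst_window(
    panel: PopulationPanel,
    width: int = 10_000,
    step: int = 5_000,
    estimator: str = "hudson",
) -> WindowProfile:
    """Windowed Fst between the two panels, ratio of averages.

    Hudson's estimator (default) per site uses
    N = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) and
    D = p1(1−p2) + p2(1−p1); the window value is ΣN / ΣD over sites with
    at least 2 calls in each population.  The Weir–Cockerham haploid
    ANOVA form is available via ``estimator="wc"``.  Reported values are
    clamped to [0, 1]; the raw ratio is kept in ``raw_values``.
    """
    p1, n1 = _site_freq(panel.pop1)
    p2, n2 = _site_freq(panel.pop2)
    usable = (n1 >= 2) & (n2 >= 2)
    if estimator == "hudson":
        num, den = _hudson_components(p1, n1, p2, n2)
    elif estimator == "wc":
        num, den = _wc_components(p1, n1, p2, n2)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)

    starts = window_starts(panel.chrom_length, width, step)
    num_sum, counts = window_aggregate(panel.positions, num, starts, width, "sum")
    den_sum, _ = window_aggregate(panel.positions, den, starts, width, "sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(
            np.isfinite(den_sum) & (den_sum != 0), num_sum / den_sum, np.nan
        )
    values = np.clip(raw, 0.0, 1.0)
    values = np.where(np.isfinite(raw), values, np.nan)
    return WindowProfile(
        panel.chrom, starts, width, step, values, counts, raw_values=raw
    )


@dataclass
class SweepCall:
    """One window of the sweep screen with its statistics and flag."""

    chrom: str
    start: int
    end: int
    fst: float
    pi_pop1: float
    pi_pop2: float
    exceeds_cutoff: bool
    cutoff_quantile: float


@dataclass
class SweepScreen:
    """Result of :func:`sweep_candidates`."""

    calls: list[SweepCall]
    fst_cutoff: float
    candidate_genes: list[str] = field(default_factory=list)

    @property
    def flagged(self) -> list[SweepCall]:
        return [c for c in self.calls if c.exceeds_cutoff]


def _as_list(x):
    return list(x) if isinstance(x, (list, tuple)) else [x]


def sweep_candidates(
    fst_profile: WindowProfile | list[WindowProfile],
    pi_dom: WindowProfile | list[WindowProfile],
    pi_wild: WindowProfile | list[WindowProfile],
    gene_models: list[GeneModel] | None = None,
    top_q: float = 0.05,
) -> SweepScreen:
    """Flag sweep windows and report overlapping candidate genes.

    A window is flagged when its Fst lies in the top ``top_q`` quantile
    (cutoff computed over all supplied profiles, i.e. the analyzed
    chromosome set) *and* its domestic-panel π is below the wild-panel π.
    Genes whose span intersects any flagged window are candidate
    domesticated genes.
    """
    fsts = _as_list(fst_profile)
    pis1 = _as_list(pi_dom)
    pis2 = _as_list(pi_wild)
    if not (len(fsts) == len(pis1) == len(pis2)):
        raise ValueError("profile lists must align")
    for f, a, b in zip(fsts, pis1, pis2):
        f.require_grid(a)
        f.require_grid(b)

    pooled = np.concatenate([f.values[np.isfinite(f.values)] for f in fsts])
    if len(pooled) == 0:
        return SweepScreen(calls=[], fst_cutoff=float("nan"))
    cutoff = float(np.quantile(pooled, 1.0 - top_q))

    calls: list[SweepCall] = []
    for f, a, b in zip(fsts, pis1, pis2):
        for i in range(len(f.starts)):
            fst = f.values[i]
            p1, p2 = a.values[i], b.values[i]
            flag = (
                np.isfinite(fst)
                and fst >= cutoff
                and np.isfinite(p1)
                and np.isfinite(p2)
                and p1 < p2
            )
            calls.append(
                SweepCall(
                    chrom=f.chrom,
                    start=int(f.starts[i]),
                    end=int(f.starts[i]) + f.width,
                    fst=float(fst),
                    pi_pop1=float(p1),
                    pi_pop2=float(p2),
                    exceeds_cutoff=bool(flag),
                    cutoff_quantile=top_q,
                )
            )

    genes: list[str] = []
    if gene_models:
        flagged = [c for c in calls if c.exceeds_cutoff]
        for gm in gene_models:
            lo, hi = gm.span
            for c in flagged:
                if c.chrom == gm.chrom and lo < c.end and c.start <= hi:
                    genes.append(gm.gene_id)
                    break
    return SweepScreen(calls=calls, fst_cutoff=cutoff, candidate_genes=sorted(set(genes)))


def allele_frequency_track(
    panel: PopulationPanel,
    interval: tuple[int, int] | None = None,
    effect_calls=None,
) -> pd.DataFrame:
    """Per-site (domestic, wild) reference-allele frequencies for plotting.

    ``interval`` is a 1-based inclusive (start, end) restriction; when
    ``effect_calls`` (from the annotation module) are supplied, sites are
    annotated with the effect class at matching positions.
    """
    f1 = allele_frequency(panel, "pop1")
    f2 = allele_frequency(panel, "pop2")
    mask = np.ones(len(panel.positions), dtype=bool)
    if interval is not None:
        lo, hi = interval
        mask = (panel.positions >= lo) & (panel.positions <= hi)
    df = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.positions[mask],
            "freq_dom": f1[mask],
            "freq_wild": f2[mask],
        }
    )
    if effect_calls is not None:
        effects = {
            (c.chrom, c.pos): c.effect for c in effect_calls if c.gene_id is not None
        }
        df["effect"] = [
            effects.get((panel.chrom, int(p)), "") for p in df["pos"]
        ]
    return df
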
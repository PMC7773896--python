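"""Index statistics, window profiles, confidence bands and region calls."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsasweep import (
    CandidateRegion,
    candidate_regions,
    delta_profile,
    intersect_regions,
    permutation_band,
    snp_index,
    window_profile,
)
from bsasweep.bsa import exceedance
from bsasweep.variant_io import MarkerTable
from bsasweep.windows import GridMismatchError


def _table(pos, bulk_pos_counts, bulk_neg_counts=None, chrom="c"):
    """Build a 2-bulk marker table from (ref, nonref) pair lists."""
    bulk_neg_counts = bulk_neg_counts or bulk_pos_counts
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "variant_type": "SNP",
            "P_P50_ref": 10,
            "P_P50_nonref": 0,
            "P_Wild_ref": 0,
            "P_Wild_nonref": 10,
            "bulk_pos_ref": [r for r, _ in bulk_pos_counts],
            "bulk_pos_nonref": [a for _, a in bulk_pos_counts],
            "bulk_neg_ref": [r for r, _ in bulk_neg_counts],
            "bulk_neg_nonref": [a for _, a in bulk_neg_counts],
        }
    )
    return MarkerTable(df, ("P_P50", "P_Wild"), ("bulk_pos", "bulk_neg"))


@pytest.mark.parametrize(
    "ref,nonref,expected",
    [(20, 0, 0.0), (0, 15, 1.0), (12, 4, 0.25), (1, 1, 0.5)],
)
def test_snp_index_values(ref, nonref, expected):
    assert snp_index(ref, nonref) == pytest.approx(expected)


def test_snp_index_zero_depth_is_missing_not_zero():
    assert np.isnan(snp_index(0, 0))


def test_window_mean_of_two_markers():
    table = _table([100_000, 500_000], [(8, 2), (4, 6)])  # indexes 0.2 and 0.6
    prof = window_profile(table, "bulk_pos", width=1_000_000, step=1_000_000,
                          chrom_length=2_000_000)
    assert prof.values[0] == pytest.approx(0.4)
    assert np.isnan(prof.values[1])  # empty window is missing, not 0
    assert prof.n_markers[1] == 0


def test_window_profile_matches_bruteforce(random_marker_table):
    """Sliding-window means equal an independent O(n x windows) loop."""
    table = random_marker_table(n=1000, seed=31)
    W, S, L = 400_000, 50_000, 5_000_000
    prof = window_profile(table, "bulk_pos", W, S, chrom_length=L)
    pos = table.positions()
    ref, nonref = table.counts("bulk_pos")
    idx = nonref / (ref + nonref)
    for w, start in enumerate(prof.starts):
        inside = (pos >= start) & (pos < start + W)
        if inside.sum() == 0:
            assert np.isnan(prof.values[w])
        else:
            assert prof.values[w] == pytest.approx(idx[inside].mean(), abs=1e-12)
        assert prof.n_markers[w] == inside.sum()


def test_delta_antisymmetry_and_grid_check(random_marker_table):
    table = random_marker_table(n=300, seed=32)
    a = window_profile(table, "bulk_pos", 200_000, 100_000, chrom_length=5_000_000)
    b = window_profile(table, "bulk_neg", 200_000, 100_000, chrom_length=5_000_000)
    d_ab = delta_profile(a, b)
    d_ba = delta_profile(b, a)
    np.testing.assert_allclose(d_ab.values, -d_ba.values, equal_nan=True)
    with pytest.raises(GridMismatchError):
        delta_profile(a, window_profile(table, "bulk_neg", 100_000, 100_000,
                                        chrom_length=5_000_000))


def test_index_and_delta_bounds(random_marker_table):
    table = random_marker_table(n=500, seed=33)
    p = window_profile(table, "bulk_pos", 100_000, 50_000, chrom_length=5_000_000)
    n = window_profile(table, "bulk_neg", 100_000, 50_000, chrom_length=5_000_000)
    d = delta_profile(p, n)
    assert np.nanmin(p.values) >= 0 and np.nanmax(p.values) <= 1
    assert np.nanmin(d.values) >= -1 and np.nanmax(d.values) <= 1


def _null_table(n, depth_mean, seed, L=20_000_000):
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(np.arange(1, L + 1), n, replace=False))
    out = []
    for _ in range(2):
        depth = np.maximum(rng.poisson(depth_mean, n), 1)
        alt = rng.binomial(depth, 0.25)
        out.append(list(zip(depth - alt, alt)))
    return _table(pos, out[0], out[1])


def test_permutation_band_median_near_zero_and_reproducible():
    table = _null_table(n=500, depth_mean=30, seed=41, L=5_000_000)
    kw = dict(width=1_000_000, step=500_000, n_perm=1000, seed=5,
              chrom_length=5_000_000)
    band = permutation_band(table, "bulk_pos", "bulk_neg", **kw)
    mid = (band.lower + band.upper) / 2
    assert np.nanmax(np.abs(mid)) < 0.02  # symmetric null, >=50 markers/window
    band2 = permutation_band(table, "bulk_pos", "bulk_neg", **kw)
    np.testing.assert_array_equal(band.upper, band2.upper)
    assert np.all(band.lower <= band.upper)


def test_band_halfwidth_scales_inverse_sqrt_marker_count():
    """Quadrupling markers per window shrinks the band roughly 2x (CLT)."""
    widths = {}
    for n in (500, 2000):
        table = _null_table(n=n, depth_mean=30, seed=43, L=10_000_000)
        band = permutation_band(table, "bulk_pos", "bulk_neg",
                                width=2_000_000, step=2_000_000,
                                n_perm=600, seed=6, chrom_length=10_000_000)
        widths[n] = np.nanmean(band.upper - band.lower)
    ratio = widths[500] / widths[2000]
    assert 1.6 < ratio < 2.5


def test_null_delta_grand_mean_near_zero():
    table = _null_table(n=2000, depth_mean=30, seed=44)
    p = window_profile(table, "bulk_pos", chrom_length=20_000_000)
    n = window_profile(table, "bulk_neg", chrom_length=20_000_000)
    d = delta_profile(p, n)
    assert abs(np.nanmean(d.values)) < 0.01


def test_candidate_regions_strict_and_peak():
    table = _null_table(n=200, depth_mean=30, seed=45, L=5_000_000)
    p = window_profile(table, "bulk_pos", 1_000_000, 500_000, chrom_length=5_000_000)
    n = window_profile(table, "bulk_neg", 1_000_000, 500_000, chrom_length=5_000_000)
    d = delta_profile(p, n)
    band = permutation_band(table, "bulk_pos", "bulk_neg", 1_000_000, 500_000,
                            n_perm=400, seed=7, chrom_length=5_000_000)
    # all-below-band null: strict call is empty
    below = exceedance(d, band, side="upper")
    if not below.any():
        assert candidate_regions(d, band, mode="strict") == []
    # a forced contiguous exceeding run spans one region
    d.values[:] = 0.0
    d.values[4:7] = 0.9
    regions = candidate_regions(d, band, mode="strict")
    assert len(regions) == 1
    assert regions[0].start == d.starts[4]
    assert regions[0].end == d.starts[6] + d.width
    assert regions[0].peak_delta == pytest.approx(0.9)
    # peak mode flags exactly the top windows
    peaks = candidate_regions(d, mode="peak", top_q=3 / len(d.values))
    assert len(peaks) == 1 and peaks[0].start == d.starts[4]


def test_intersect_regions_examples():
    mb = 1_000_000
    a = [CandidateRegion("chr19", 3 * mb, 5 * mb, 0.4, 10, "white")]
    b = [CandidateRegion("chr19", 1 * mb, 5 * mb, 0.35, 20, "dark")]
    out = intersect_regions(a, b)
    assert len(out) == 1
    assert (out[0].start, out[0].end) == (3 * mb, 5 * mb)
    # disjoint -> empty
    c = [CandidateRegion("chr19", 6 * mb, 7 * mb, 0.2, 3)]
    assert intersect_regions(a, c) == []
    # self-intersection is identity on intervals
    aa = intersect_regions(a, a)
    assert (aa[0].start, aa[0].end) == (a[0].start, a[0].end)


@settings(derandomize=True, max_examples=25)
@given(
    ref=st.integers(min_value=0, max_value=1000),
    nonref=st.integers(min_value=0, max_value=1000),
)
def test_snp_index_always_in_unit_interval(ref, nonref):
    idx = snp_index(ref, nonref)
    if ref + nonref == 0:
        assert np.isnan(idx)
    else:
        assert 0.0 <= idx <= 1.0
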
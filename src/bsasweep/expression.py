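"""FPKM-table utilities: heatmap z-scoring and the brain-expression test.

Heatmaps are drawn on per-gene z-scores; between-strain comparisons use
library-depth–rescaled FPKM and a classical equal-variance two-sample
Student's t-test per gene, with no multiple-testing correction.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["zscore_rows", "depth_normalize", "depth_normalize_and_test"]


def zscore_rows(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-scores: (x − row mean) / row sd (sample sd, ddof 1).

    Constant rows come back as all zeros and are flagged in the returned
    boolean Series.  Requires at least 2 samples per row.
    """
    if table.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples per gene")
    mean = table.mean(axis=1)
    sd = table.std(axis=1, ddof=1)
    constant = sd == 0
    z = table.sub(mean, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    return z, constant


def depth_normalize(
    table: pd.DataFrame,
    library_depths: pd.Series,
    reference_depth: float | None = None,
) -> pd.DataFrame:
    """Rescale each sample's FPKM by (reference depth / its library depth).

    ``library_depths`` maps sample label → total mapped reads; the
    reference depth defaults to the mean depth over the table's samples.
    """
    depths = library_depths.reindex(table.columns)
    if depths.isna().any():
        missing = list(depths.index[depths.isna()])
        raise KeyError(f"no library depth for samples {missing}")
    if reference_depth is None:
        reference_depth = float(depths.mean())
    return table.mul(reference_depth / depths, axis=1)


def depth_normalize_and_test(
    table: pd.DataFrame,
    library_depths: pd.Series,
    group_a: list[str],
    group_b: list[str],
    reference_depth: float | None = None,
) -> pd.DataFrame:
    """Depth-normalize, then Student's t-test (equal variance) per gene.

    Returns a table indexed by gene with the group means, t statistic and
    two-sided p-value.  Fewer than 2 replicates in a group gives a
    missing p-value; zero variance in both groups with equal means gives
    t = 0, p = 1 (flagged in the ``degenerate`` column).
    """
    norm = depth_normalize(table, library_depths, reference_depth)
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)

    out = pd.DataFrame(index=table.index)
    out["mean_a"] = a.mean(axis=1) if a.shape[1] else np.nan
    out["mean_b"] = b.mean(axis=1) if b.shape[1] else np.nan
    out["t"] = np.nan
    out["pvalue"] = np.nan
    out["degenerate"] = False
    if a.shape[1] < 2 or b.shape[1] < 2:
        return out

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision warning; the degenerate
        # cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    out["t"] = t
    out["pvalue"] = p

    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    fix = degenerate & equal_means
    out.loc[fix, "t"] = 0.0
    out.loc[fix, "pvalue"] = 1.0
    out.loc[degenerate, "degenerate"] = True
    return out
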
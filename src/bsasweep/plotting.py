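"""Plot helpers for the CLI: Δ-index tracks and sweep signature panels."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

import numpy as np  # noqa: E402

from .bsa import ThresholdBand  # noqa: E402
from .windows import WindowProfile  # noqa: E402


def _mb(x):
    return np.asarray(x, dtype=float) / 1e6


def plot_delta(profile: WindowProfile, band: ThresholdBand | None, path) -> None:
    """ΔSNP/InDel-index track with the confidence band, saved as PNG."""
    fig, ax = plt.subplots(figsize=(9, 3))
    mid = _mb(profile.starts + profile.width / 2)
    ax.plot(mid, profile.values, color="black", lw=0.8)
    if band is not None:
        ax.plot(mid, band.upper, color="tab:blue", lw=0.8)
        ax.plot(mid, band.lower, color="tab:blue", lw=0.8)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"{profile.chrom} position (Mb)")
    ax.set_ylabel("Δ index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sweep(
    fst: WindowProfile,
    pi_dom: WindowProfile,
    pi_wild: WindowProfile,
    cutoff: float,
    path,
) -> None:
    """Two-panel sweep figure: Fst with its cutoff, π per population."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(9, 5), sharex=True)
    mid = _mb(fst.starts + fst.width / 2)
    ax1.plot(mid, fst.values, color="black", lw=0.8)
    ax1.axhline(cutoff, color="red", lw=0.8, label="top-quantile cutoff")
    ax1.set_ylabel("Fst")
    ax1.legend(frameon=False, fontsize=8)
    ax2.plot(mid, pi_dom.values, color="tab:blue", lw=0.8, label="domestic π")
    ax2.plot(mid, pi_wild.values, color="black", lw=0.8, label="wild π")
    ax2.set_ylabel("π per bp")
    ax2.set_xlabel(f"{fst.chrom} position (Mb)")
    ax2.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
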
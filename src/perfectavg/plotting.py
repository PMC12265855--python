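"""Three-panel diagnostic plot: mean intensity, SNR, spectral entropy."""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Union

import matplotlib

matplotlib.use("Agg")  # file output only; never requires a display

import matplotlib.pyplot as plt
import numpy as np

if TYPE_CHECKING:
    from .pipeline import SelectionResult

__all__ = ["diagnostic_plot"]


def diagnostic_plot(result: "SelectionResult", path: Union[str, Path]) -> Path:
    """Save the standard diagnostic figure for one analysis run.

    Top: normalized per-frame mean intensity with the fitted bleaching
    curve.  Middle: SNR per averaging level (log2 x-axis) with the
    SNR-optimal level marked.  Bottom: normalized and smoothed spectral
    entropy with the PSD-optimal level marked.
    """
    path = Path(path)
    n_avg = np.asarray(result.averaged.n_averaged, dtype=float)

    fig, (ax_int, ax_snr, ax_ent) = plt.subplots(3, 1, figsize=(7, 9), sharex=False)

    t = np.arange(len(result.trace.means))
    ax_int.plot(t, result.trace.normalized, ".", ms=3, color="0.4", label="measured")
    fit = result.bleach_fit
    if fit.converged and (fit.a + fit.c) > 0:
        ax_int.plot(t, fit.curve(t) / (fit.a + fit.c), "-", color="crimson", label="fitted decay")
    ax_int.set_xlabel("frame index t")
    ax_int.set_ylabel("normalized mean intensity")
    ax_int.legend(loc="best", fontsize=8)

    snr_vals = np.where(np.isinf(result.snr_per_level), np.nan, result.snr_per_level)
    ax_snr.plot(n_avg, snr_vals, "o-", color="magenta")
    ax_snr.axvline(2**result.snr_optimal_k, color="magenta", ls="--", lw=1,
                   label=f"SNR-optimal: {2**result.snr_optimal_k} averages")
    ax_snr.set_xscale("log", base=2)
    ax_snr.set_xlabel("frames averaged")
    ax_snr.set_ylabel("SNR")
    ax_snr.legend(loc="best", fontsize=8)

    if result.entropy_series is not None:
        ax_ent.plot(n_avg, result.entropy_series.H_norm, "o-", color="0.5", label="normalized entropy")
        ax_ent.plot(n_avg, result.entropy_series.smoothed, "-", color="teal", label="smoothed")
        if result.psd_optimal_k is not None:
            ax_ent.axvline(2**result.psd_optimal_k, color="teal", ls="--", lw=1,
                           label=f"PSD-optimal: {2**result.psd_optimal_k} averages")
        ax_ent.set_xscale("log", base=2)
        ax_ent.legend(loc="best", fontsize=8)
    else:
        ax_ent.text(0.5, 0.5, "PSD analysis unavailable (degenerate spectrum)",
                    ha="center", va="center", transform=ax_ent.transAxes)
    ax_ent.set_xlabel("frames averaged")
    ax_ent.set_ylabel("spectral entropy (normalized)")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
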
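"""End-to-end analysis: from an xyt stack to an averaging recommendation.

The workflow mirrors how a microscopist would use a pilot acquisition:

1. fit the exponential photobleaching model to the per-frame mean trace;
2. (optionally) correct the stack for the fitted decay;
3. build the geometric averaging series 2^0 .. 2^K;
4. score every level by SNR and by normalized spectral entropy;
5. mark levels ineligible when their last constituent raw frame has
   bleached past the user's acceptable limit (an average contaminated by
   over-bleached frames should not be recommended);
6. report the SNR-optimal level (max SNR among eligible levels, ties to
   fewer frames), the PSD-optimal level (entropy plateau start), and the
   conservative headline recommendation min(SNR-optimal, PSD-optimal).

SNR and entropy are computed on bleach-CORRECTED frames by default so the
decay trend cannot masquerade as an SNR or spectral change; eligibility is
always judged on the UNcorrected fit, since it expresses how much real
signal has been lost.  Outputs are the averaged multipage TIFF (one page
per level, float32), a three-panel diagnostic plot, and a flat JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from .averaging import AveragedSeries, geometric_average
from .metrics import (
    BleachFit,
    IntensityTrace,
    bleach_eligibility,
    correct_bleach,
    fit_bleach,
    mean_trace,
    snr,
)
from .spectral import (
    DegenerateSpectrumError,
    EntropySeries,
    StabilityResult,
    detect_stability,
    entropy_series,
)
from .stack_io import ImageStack, crop_center, write_stack

__all__ = ["Config", "SelectionResult", "select_snr_optimal", "run_pipeline", "crop_sweep"]


@dataclass(frozen=True)
class Config:
    """User-facing analysis parameters.

    ``bleach_limit_pct`` is the acceptable photobleaching as a percentage
    drop of the fitted normalized intensity (0 = no drop tolerated);
    ``psd_threshold`` the entropy-plateau stability threshold on the
    min-max-rescaled smoothed series (0.1 is the recommended default);
    ``smooth_window`` the odd moving-average width over levels.
    """

    bleach_limit_pct: float = 0.0
    psd_threshold: float = 0.1
    smooth_window: int = 5
    apply_bleach_correction: bool = True
    exclude_dc: bool = False
    out_dir: Union[str, Path, None] = None

    def __post_init__(self) -> None:
        if not 0 <= self.bleach_limit_pct <= 100:
            raise ValueError(f"bleach_limit_pct must be in [0, 100], got {self.bleach_limit_pct}")
        if self.psd_threshold <= 0:
            raise ValueError(f"psd_threshold must be > 0, got {self.psd_threshold}")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError(f"smooth_window must be odd >= 1, got {self.smooth_window}")


@dataclass(frozen=True)
class SelectionResult:
    """Everything the analysis decided, plus the per-level evidence."""

    snr_optimal_k: int
    psd_optimal_k: int | None
    recommended_k: int
    snr_per_level: np.ndarray
    entropy_series: EntropySeries | None
    bleach_fit: BleachFit
    trace: IntensityTrace
    averaged: AveragedSeries
    eligibility_per_level: np.ndarray
    no_plateau: bool
    warnings: tuple[str, ...] = ()

    @property
    def snr_optimal_averages(self) -> int:
        return 2**self.snr_optimal_k

    @property
    def psd_optimal_averages(self) -> int | None:
        return None if self.psd_optimal_k is None else 2**self.psd_optimal_k

    @property
    def recommended_averages(self) -> int:
        return 2**self.recommended_k


def select_snr_optimal(
    snr_per_level: Sequence[float], eligibility_per_level: Sequence[bool]
) -> tuple[int, bool]:
    """Exponent of the maximum-SNR level among bleach-eligible levels.

    The infinite-SNR safeguard sentinel ranks above every finite value;
    ties break toward the SMALLEST exponent (fewer frames, shorter
    acquisition).  Returns ``(k, none_eligible)``; when no level is
    eligible, ``(0, True)``.
    """
    snrs = list(snr_per_level)
    elig = list(eligibility_per_level)
    if len(snrs) != len(elig):
        raise ValueError(f"length mismatch: {len(snrs)} SNR values vs {len(elig)} eligibility flags")
    if not snrs:
        raise ValueError("need at least one level")
    best: int | None = None
    for k, (s, e) in enumerate(zip(snrs, elig)):
        if e and (best is None or s > snrs[best]):  # strict > keeps earliest on ties
            best = k
    if best is None:
        return 0, True
    return best, False


def run_pipeline(stack: ImageStack, config: Config = Config()) -> SelectionResult:
    """Run the full analysis on one stack; write outputs if ``out_dir`` set.

    Outputs (under ``config.out_dir``): ``averaged.tif`` (one float32 page
    per level, ascending), ``analysis.png`` (normalized mean intensity, SNR
    and spectral entropy with the optima marked), ``report.json`` (config
    echo, fit parameters, per-level values, selections, warnings).
    """
    warns: list[str] = []

    trace = mean_trace(stack)
    if stack.n_frames >= 4:
        fit = fit_bleach(trace)
        if not fit.converged:
            warns.append("bleach fit did not converge; proceeding uncorrected")
    else:
        fit = BleachFit(a=0.0, b=0.0, c=float(trace.means[0]), converged=False, rss=0.0)
        warns.append("fewer than 4 frames: bleach fit skipped")

    if config.apply_bleach_correction and fit.converged:
        working = correct_bleach(stack, fit)
    else:
        working = stack

    averaged = geometric_average(working)
    snr_per_level = np.array([snr(img) for img in averaged.images])

    ent: EntropySeries | None
    no_plateau = False
    try:
        ent = entropy_series(averaged, window=config.smooth_window, exclude_dc=config.exclude_dc)
        if averaged.n_levels >= 2:
            stab = detect_stability(ent.smoothed, threshold=config.psd_threshold)
            psd_optimal_k = int(averaged.levels[stab.index])
            no_plateau = not stab.plateau_found
            if no_plateau:
                warns.append("no sustained spectral-entropy plateau; last level reported")
        else:
            psd_optimal_k = int(averaged.levels[0])
    except DegenerateSpectrumError as exc:
        ent = None
        psd_optimal_k = None
        warns.append(f"PSD analysis aborted: {exc}; SNR criterion still reported")

    frame_elig = bleach_eligibility(fit, stack.n_frames, config.bleach_limit_pct)
    eligibility_per_level = frame_elig[averaged.last_source_frame]
    snr_optimal_k, none_eligible = select_snr_optimal(snr_per_level, eligibility_per_level)
    if none_eligible:
        warns.append("no averaging level met the photobleaching limit; defaulting to level 0")

    recommended_k = snr_optimal_k if psd_optimal_k is None else min(snr_optimal_k, psd_optimal_k)

    result = SelectionResult(
        snr_optimal_k=snr_optimal_k,
        psd_optimal_k=psd_optimal_k,
        recommended_k=recommended_k,
        snr_per_level=snr_per_level,
        entropy_series=ent,
        bleach_fit=fit,
        trace=trace,
        averaged=averaged,
        eligibility_per_level=eligibility_per_level,
        no_plateau=no_plateau,
        warnings=tuple(warns),
    )

    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _result_report(result: SelectionResult, config: Config) -> dict:
    """Flat, JSON-serializable report of one analysis run."""

    def _num(v: float) -> float | str:
        return "inf" if math.isinf(v) else float(v)

    ent = result.entropy_series
    return {
        "config": {
            "bleach_limit_pct": config.bleach_limit_pct,
            "psd_threshold": config.psd_threshold,
            "smooth_window": config.smooth_window,
            "apply_bleach_correction": config.apply_bleach_correction,
            "exclude_dc": config.exclude_dc,
        },
        "bleach_fit": {
            "a": result.bleach_fit.a,
            "b": result.bleach_fit.b,
            "c": result.bleach_fit.c,
            "converged": result.bleach_fit.converged,
            "rss": result.bleach_fit.rss,
        },
        "levels": [int(k) for k in result.averaged.levels],
        "n_averaged": [int(n) for n in result.averaged.n_averaged],
        "snr_per_level": [_num(s) for s in result.snr_per_level],
        "entropy_norm_per_level": None if ent is None else [float(h) for h in ent.H_norm],
        "entropy_smoothed_per_level": None if ent is None else [float(h) for h in ent.smoothed],
        "eligibility_per_level": [bool(e) for e in result.eligibility_per_level],
        "snr_optimal_k": result.snr_optimal_k,
        "snr_optimal_averages": result.snr_optimal_averages,
        "psd_optimal_k": result.psd_optimal_k,
        "psd_optimal_averages": result.psd_optimal_averages,
        "recommended_k": result.recommended_k,
        "recommended_averages": result.recommended_averages,
        "no_plateau": result.no_plateau,
        "warnings": list(result.warnings),
    }


def _write_outputs(result: SelectionResult, config: Config) -> None:
    from .plotting import diagnostic_plot  # deferred: matplotlib import is slow

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_stack(
        ImageStack(frames=result.averaged.images), out_dir / "averaged.tif", bit_depth="float32"
    )
    diagnostic_plot(result, out_dir / "analysis.png")
    report = _result_report(result, config)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def crop_sweep(
    stack: ImageStack, sides: Sequence[int], config: Config = Config()
) -> list[dict]:
    """Re-run the analysis on center crops of several sizes.

    Returns one row per side: ``{"side", "snr_optimal_k", "psd_optimal_k",
    "recommended_k", ...}``.  Used to probe how small a region of interest
    can get before the recommendation changes.  If ``config.out_dir`` is
    set, writes ``crop_sweep.csv`` there (per-crop TIFF/plot outputs are
    suppressed).
    """
    sub_config = dataclasses.replace(config, out_dir=None)
    rows = []
    for side in sides:
        res = run_pipeline(crop_center(stack, side), sub_config)
        rows.append(
            {
                "side": int(side),
                "snr_optimal_k": res.snr_optimal_k,
                "snr_optimal_averages": res.snr_optimal_averages,
                "psd_optimal_k": res.psd_optimal_k,
                "psd_optimal_averages": res.psd_optimal_averages,
                "recommended_k": res.recommended_k,
                "recommended_averages": res.recommended_averages,
                "no_plateau": res.no_plateau,
            }
        )
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = list(rows[0].keys())
        lines = [",".join(header)]
        lines += [",".join(str(r[h]) for h in header) for r in rows]
        (out_dir / "crop_sweep.csv").write_text("\n".join(lines) + "\n")
    return rows
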
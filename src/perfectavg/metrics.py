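"""Image SNR, frame-mean intensity trace, and photobleaching model.

SNR of a single image is mu / sigma, the mean over the population standard
deviation (divisor N) of its pixel values.  Constant images are valid
degenerate input: a zero-noise safeguard returns ``math.inf`` instead of
raising, and selection treats that sentinel as larger than any finite SNR.

Photobleaching is modeled as an exponential decay of the per-frame mean
intensity,

    I(t) = a * exp(-b * t) + c,       a, b, c >= 0,

fitted by bounded nonlinear least squares.  Correction multiplies frame t
by the single scalar (a + c) / (a*exp(-b*t) + c), which restores the fitted
mean to its t = 0 value while keeping intensities within a frame
proportional to the originals.  Eligibility under a user bleaching limit is
evaluated on the FITTED curve, not on raw noisy means, so random
fluctuations cannot disqualify individual frames.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import f as f_dist

from .stack_io import ImageStack

__all__ = [
    "IntensityTrace",
    "BleachFit",
    "snr",
    "mean_trace",
    "fit_bleach",
    "correct_bleach",
    "bleach_eligibility",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame spatial mean intensity, raw and normalized to frame 0."""

    means: np.ndarray
    normalized: np.ndarray


@dataclass(frozen=True)
class BleachFit:
    """Fitted a*exp(-b*t) + c decay with diagnostics.

    ``converged`` is False when the solver failed and the identity fit
    (a=0, b=0, c=means[0]) was substituted; ``rss`` is the residual sum of
    squares of the returned parameters against the fitted trace.
    ``decay_significant`` is False when the exponential did not improve on
    a constant fit (F-test): the trace shows no detectable bleaching and
    the flat fit (a=0, b=0, c=mean) is returned in its place, so correction
    and eligibility reduce to the identity.
    """

    a: float
    b: float
    c: float
    converged: bool
    rss: float
    decay_significant: bool = True

    def curve(self, t: np.ndarray | float) -> np.ndarray:
        """Fitted mean intensity at frame index t."""
        return _decay(np.asarray(t, dtype=np.float64), self.a, self.b, self.c)


def _decay(t, a, b, c):
    return a * np.exp(-b * t) + c


def snr(image: np.ndarray) -> float:
    """mu / sigma of the pixel values of one image (population sigma).

    Returns ``math.inf`` when sigma is below ``1e-12 * max(1, |mu|)`` (the
    zero-noise safeguard): a constant image has no measurable noise, and the
    sentinel ranks above every finite SNR in downstream selection.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot compute SNR of an empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    mu = float(image.mean())
    sigma = float(image.std())  # divisor N
    if sigma < 1e-12 * max(1.0, abs(mu)):
        logger.debug("zero-noise safeguard triggered (mu=%g)", mu)
        return math.inf
    return mu / sigma


def mean_trace(stack: ImageStack) -> IntensityTrace:
    """Spatial mean of each frame, plus the frame-0-normalized trace."""
    means = stack.frames.mean(axis=(1, 2))
    if means[0] != 0:
        normalized = means / means[0]
    else:
        # degenerate zero first frame: normalization undefined, use ones
        warnings.warn("first frame has zero mean; normalized trace set to 1", stacklevel=2)
        normalized = np.ones_like(means)
    return IntensityTrace(means=means, normalized=normalized)


def fit_bleach(trace: IntensityTrace) -> BleachFit:
    """Fit the exponential decay model to a mean-intensity trace.

    Least squares of ``a*exp(-b*t) + c`` against ``trace.means`` at
    ``t = 0 .. n-1``, with all three parameters bounded below by zero so the
    fitted curve is nonincreasing (the model describes decay; an intensity
    rise is out of model).  Initial guesses: ``a0 = means[0] - min(means)``,
    ``b0 = 1/n``, ``c0 = min(means)``.  On solver failure the identity fit
    ``(0, 0, means[0])`` is returned with ``converged=False``.

    A trace with no real photobleaching still yields a tiny spurious decay
    from sampling noise, which would wrongly disqualify frames under a
    strict (e.g. 0%) bleaching limit.  The fitted exponential is therefore
    compared against a constant fit with a nested-model F-test (2 extra
    parameters, alpha = 0.05); when the improvement is not significant the
    flat fit ``(0, 0, mean(means))`` is returned with
    ``decay_significant=False``.
    """
    means = np.asarray(trace.means, dtype=np.float64)
    n = means.size
    if n < 4:
        raise ValueError(f"need at least 4 frames to fit 3 parameters, got {n}")
    t = np.arange(n, dtype=np.float64)
    a0 = max(float(means[0] - means.min()), 0.0)
    b0 = 1.0 / n
    c0 = float(means.min())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # covariance warnings on degenerate fits
            popt, _ = curve_fit(
                _decay,
                t,
                means,
                p0=(a0, b0, c0),
                bounds=(0.0, np.inf),
                method="trf",
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
                max_nfev=20000,
            )
        a, b, c = (float(v) for v in popt)
        converged = all(math.isfinite(v) for v in (a, b, c))
    except (RuntimeError, ValueError):
        a, b, c, converged = 0.0, 0.0, float(means[0]), False
    if not converged:
        a, b, c = 0.0, 0.0, float(means[0])
        rss = float(np.sum((means - _decay(t, a, b, c)) ** 2))
        return BleachFit(a=a, b=b, c=c, converged=False, rss=rss)

    rss = float(np.sum((means - _decay(t, a, b, c)) ** 2))
    # nested-model check: is the exponential better than a constant?
    c_const = float(means.mean())
    rss_const = float(np.sum((means - c_const) ** 2))
    if rss > 0:
        f_stat = ((rss_const - rss) / 2.0) / (rss / (n - 3))
        significant = f_stat > 0 and float(f_dist.sf(f_stat, 2, n - 3)) < 0.05
    else:
        # perfect exponential fit: significant unless the trace is constant
        significant = rss_const > 0
    if not significant:
        return BleachFit(
            a=0.0, b=0.0, c=c_const, converged=True, rss=rss_const, decay_significant=False
        )
    return BleachFit(a=a, b=b, c=c, converged=True, rss=rss)


def correct_bleach(stack: ImageStack, fit: BleachFit) -> ImageStack:
    """Rescale each frame by the inverse of the fitted, normalized decay.

    Frame t is multiplied by ``f(t) = (a + c) / (a*exp(-b*t) + c)``; f(0)
    is exactly 1, so the first frame is unchanged, and each frame is scaled
    by a single scalar so within-frame intensity ratios are preserved.  A
    non-converged fit passes the stack through unchanged with a warning.
    """
    if not fit.converged:
        warnings.warn("bleach fit did not converge; stack returned uncorrected", stacklevel=2)
        return stack
    if fit.a + fit.c <= 0:
        warnings.warn("fitted curve is identically zero; stack returned uncorrected", stacklevel=2)
        return stack
    t = np.arange(stack.n_frames, dtype=np.float64)
    denom = fit.curve(t)
    if np.any(denom <= 0):
        raise ValueError("pathological bleach fit: fitted intensity <= 0; correction aborted")
    factors = (fit.a + fit.c) / denom
    return replace(stack, frames=stack.frames * factors[:, None, None])


def bleach_eligibility(fit: BleachFit, n_frames: int, limit_pct: float) -> np.ndarray:
    """Boolean mask of frames whose FITTED intensity stays within the limit.

    Frame t is eligible iff the fitted normalized intensity
    ``(a*exp(-b*t) + c) / (a + c)`` is at least ``1 - limit_pct/100``
    (minus a 1e-9 guard for boundary stability).  Since the fitted curve is
    nonincreasing, eligibility is monotone: once a frame fails, all later
    frames fail.
    """
    if not 0 <= limit_pct <= 100:
        raise ValueError(f"bleach limit must be in [0, 100] percent, got {limit_pct}")
    t = np.arange(n_frames, dtype=np.float64)
    if fit.a + fit.c <= 0:
        return np.ones(n_frames, dtype=bool)  # zero trace: nothing to bleach
    norm = fit.curve(t) / (fit.a + fit.c)
    return norm >= 1.0 - limit_pct / 100.0 - 1e-9
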
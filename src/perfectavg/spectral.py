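"""Power spectra, spectral entropy, smoothing, and plateau detection.

The 2D power spectrum of an image is P(u, v) = |F(u, v)|^2 with the
zero-frequency component shifted to the center (no windowing, no
detrending, DC included).  Normalizing P to unit sum gives a probability
distribution over spatial-frequency bins; its Shannon entropy

    H = -sum_i p_i ln p_i        (nats)

measures how spread out the image's power is across frequencies: H = 0 for
power concentrated in a single bin, H = ln(M) for a perfectly flat
spectrum over M bins.  White noise has a flat spectrum, structure
concentrates power at low frequencies, so averaging away noise drives the
normalized entropy H / ln(M) down until only the structure remains --
the per-level entropy curve plateaus once further averaging stops adding
information, and the plateau start is the PSD-optimal averaging level.

Plateau detection: the smoothed entropy series is min-max rescaled to
[0, 1] (so the threshold has a scale-free meaning), and the returned index
is the first level from which EVERY subsequent step is smaller than the
threshold -- a sustained plateau, not a first crossing, because a single
small step can occur well before true stabilization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .averaging import AveragedSeries

__all__ = [
    "DegenerateSpectrumError",
    "PowerSpectrum",
    "EntropySeries",
    "StabilityResult",
    "power_spectrum",
    "spectral_entropy",
    "entropy_series",
    "smooth",
    "detect_stability",
]


class DegenerateSpectrumError(ValueError):
    """Total spectral power is zero; probabilities are undefined."""


@dataclass(frozen=True)
class PowerSpectrum:
    """Centered 2D power spectrum and its unit-sum normalization."""

    power: np.ndarray
    probabilities: np.ndarray


@dataclass(frozen=True)
class EntropySeries:
    """Per-averaging-level spectral entropy: raw (nats), normalized, smoothed."""

    levels: np.ndarray
    H: np.ndarray
    H_norm: np.ndarray
    smoothed: np.ndarray


class StabilityResult(NamedTuple):
    index: int
    plateau_found: bool


def power_spectrum(image: np.ndarray) -> PowerSpectrum:
    """|FFT2(image)|^2 with DC at the center, plus unit-sum probabilities."""
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot compute the power spectrum of an empty image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    power = np.abs(np.fft.fftshift(np.fft.fft2(image))) ** 2
    total = power.sum()
    if total <= 0:
        raise DegenerateSpectrumError("total spectral power is zero (all-zero image)")
    return PowerSpectrum(power=power, probabilities=power / total)


def spectral_entropy(ps: PowerSpectrum, exclude_dc: bool = False) -> tuple[float, float]:
    """Shannon entropy of a power spectrum, in nats, and its normalized form.

    Returns ``(H, H_norm)`` with ``H = -sum p_i ln p_i`` over all M bins
    (convention 0 ln 0 = 0) and ``H_norm = H / ln M`` in [0, 1].  With
    ``exclude_dc`` the centered zero-frequency bin is dropped and the
    remaining power renormalized (M becomes the bin count minus one).
    """
    p = ps.probabilities
    if exclude_dc:
        h, w = p.shape
        mask = np.ones_like(p, dtype=bool)
        mask[h // 2, w // 2] = False
        p = p[mask]
        total = p.sum()
        if total <= 0:
            raise DegenerateSpectrumError("no power outside the DC bin")
        p = p / total
    p = np.asarray(p).ravel()
    nz = p[p > 0]
    H = float(-(nz * np.log(nz)).sum())
    M = p.size
    H_norm = H / math.log(M) if M > 1 else 0.0
    return H, H_norm


def entropy_series(
    series: AveragedSeries, window: int = 5, exclude_dc: bool = False
) -> EntropySeries:
    """Spectral entropy of every averaging level, smoothed for stability.

    ``window`` is the centered moving-average width applied to the
    normalized entropies (see :func:`smooth`).
    """
    H = np.empty(series.n_levels)
    H_norm = np.empty(series.n_levels)
    for i, img in enumerate(series.images):
        H[i], H_norm[i] = spectral_entropy(power_spectrum(img), exclude_dc=exclude_dc)
    return EntropySeries(
        levels=np.asarray(series.levels).copy(),
        H=H,
        H_norm=H_norm,
        smoothed=smooth(H_norm, window=window),
    )


def smooth(values: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving average with symmetrically shrinking edge windows.

    At position i the half-width is ``min(window // 2, i, n - 1 - i)``, so
    the window stays centered and shrinks near the boundaries instead of
    padding; output length equals input length.  ``window`` must be odd
    (a well-defined center) and >= 1; window 1 is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = x[i - h : i + h + 1].mean()
    return out


def detect_stability(smoothed: Sequence[float], threshold: float = 0.1) -> StabilityResult:
    """First averaging level from which the entropy series stays flat.

    The input is min-max rescaled to [0, 1] (a constant series returns
    index 0 immediately), then the smallest index ``i >= 1`` is returned
    such that every subsequent step ``|s[j+1] - s[j]|`` for ``j >= i`` is
    below ``threshold`` -- the start of a sustained plateau.  If no level
    sustains the plateau, the last index is returned with
    ``plateau_found=False``.  Raising the threshold can only move the
    returned index earlier (greater tolerance to minor fluctuations).
    """
    x = np.asarray(smoothed, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 points to detect stability, got {n}")
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return StabilityResult(index=0, plateau_found=True)
    s = (x - lo) / (hi - lo)
    d = np.abs(np.diff(s))
    for i in range(1, n - 1):
        if np.all(d[i:] < threshold):
            return StabilityResult(index=i, plateau_found=True)
    return StabilityResult(index=n - 1, plateau_found=False)
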
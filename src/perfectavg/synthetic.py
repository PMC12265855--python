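"""Synthetic xyt stacks with the statistics of an un-averaged LSFM series.

Real laser scanning fluorescence data is a fixed underlying scene plus
per-frame uncorrelated detector noise, optionally attenuated over time by
photobleaching.  The generator here reproduces exactly that structure:

    frame(t) = envelope(t) * base + N(0, sigma^2)   per pixel, i.i.d.

with ``envelope(t) = (a*exp(-b*t) + c) / (a + c)`` (so envelope(0) = 1) or
identically 1 when no bleaching is requested.  Noise models detector noise,
which does not bleach, so the envelope multiplies the base only.

By default frames are NOT clipped: float frames keep the Gaussian noise
exact so the sqrt(n) averaging law holds to sampling error.  Pass
``clip_range=(0, 255)`` to emulate storage of the noisy instances as 8-bit
data (clipping plus downstream quantization at TIFF export).

Frames are drawn from one seeded generator in index order, so a spec with a
smaller ``n_frames`` produces a prefix of the longer series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack_io import ImageStack

__all__ = ["NoisySeriesSpec", "bleach_envelope", "make_phantom", "make_noisy_series"]


@dataclass(frozen=True)
class NoisySeriesSpec:
    """Recipe for a noisy series: frame count, noise scale, seed, options.

    ``bleach`` is an optional ``(a, b, c)`` triple of exponential-decay
    envelope parameters (amplitude, per-frame rate, offset); ``clip_range``
    an optional ``(lo, hi)`` intensity clamp applied after adding noise.
    Same spec + same seed is bit-identical.
    """

    n_frames: int
    sigma: float = 10.0
    seed: int = 0
    clip_range: tuple[float, float] | None = None
    bleach: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.clip_range is not None and self.clip_range[0] >= self.clip_range[1]:
            raise ValueError(f"empty clip range {self.clip_range}")
        if self.bleach is not None:
            a, b, c = self.bleach
            if a < 0 or b < 0 or c < 0 or (a + c) <= 0:
                raise ValueError(f"bleach parameters must be >= 0 with a + c > 0, got {self.bleach}")


def bleach_envelope(t: np.ndarray | float, a: float, b: float, c: float) -> np.ndarray:
    """Normalized exponential photobleaching envelope, equal to 1 at t = 0."""
    t = np.asarray(t, dtype=np.float64)
    return (a * np.exp(-b * t) + c) / (a + c)


def make_phantom(height: int, width: int, seed: int = 0) -> np.ndarray:
    """Deterministic structured 8-bit-range test image.

    A smooth diagonal gradient overlaid with filled rectangles, filled
    disks and a sinusoidal texture patch, giving spatial-frequency content
    at several scales.  Values lie in [0, 255] (float).  Same
    ``(height, width, seed)`` always yields the identical image.
    """
    if height < 8 or width < 8:
        raise ValueError(f"phantom needs height, width >= 8, got {height}x{width}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)

    img = 40.0 + 80.0 * (yy / max(height - 1, 1) + xx / max(width - 1, 1)) / 2.0

    # filled rectangles at assorted scales and intensities
    for _ in range(6):
        h = int(rng.integers(height // 8, max(height // 2, height // 8 + 1)))
        w = int(rng.integers(width // 8, max(width // 2, width // 8 + 1)))
        r = int(rng.integers(0, height - h + 1))
        c = int(rng.integers(0, width - w + 1))
        img[r : r + h, c : c + w] += float(rng.uniform(-60.0, 90.0))

    # filled disks
    for _ in range(5):
        cy = float(rng.uniform(0, height))
        cx = float(rng.uniform(0, width))
        rad = float(rng.uniform(min(height, width) / 16.0, min(height, width) / 5.0))
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
        img[mask] += float(rng.uniform(-50.0, 80.0))

    # sinusoidal texture patch: mid/high spatial frequencies
    fy = float(rng.uniform(4.0, 10.0))
    fx = float(rng.uniform(4.0, 10.0))
    img += 15.0 * np.sin(2 * np.pi * fy * yy / height) * np.cos(2 * np.pi * fx * xx / width)

    return np.clip(img, 0.0, 255.0)


def make_noisy_series(base: np.ndarray, spec: NoisySeriesSpec) -> ImageStack:
    """Replicate ``base`` into ``spec.n_frames`` noisy frames.

    Each frame is ``envelope(t) * base`` plus i.i.d. Gaussian noise of
    standard deviation ``spec.sigma``, then clipped to ``spec.clip_range``
    if one is given.  With ``sigma = 0`` and no bleaching every frame
    equals ``base`` exactly.
    """
    base = np.asarray(base, dtype=np.float64)
    if base.ndim != 2:
        raise ValueError(f"base must be 2D, got shape {base.shape}")
    if not np.all(np.isfinite(base)):
        raise ValueError("base contains non-finite values")

    rng = np.random.default_rng(spec.seed)
    if spec.bleach is not None:
        env = bleach_envelope(np.arange(spec.n_frames), *spec.bleach)
    else:
        env = np.ones(spec.n_frames)

    frames = np.empty((spec.n_frames, *base.shape), dtype=np.float64)
    for t in range(spec.n_frames):  # index order => n_frames prefixes agree
        frame = env[t] * base
        if spec.sigma > 0:
            frame = frame + rng.normal(0.0, spec.sigma, size=base.shape)
        frames[t] = frame
    if spec.clip_range is not None:
        np.clip(frames, spec.clip_range[0], spec.clip_range[1], out=frames)
    return ImageStack(frames=frames, source_bit_depth=None)
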
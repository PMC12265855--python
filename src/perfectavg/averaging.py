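"""Geometric series of progressively averaged images: 2^0, 2^1, ..., 2^K.

Averaging n uncorrelated-noise frames suppresses the noise standard
deviation by sqrt(n); doubling the frame count per step samples that law
evenly on a log axis.  Level k holds the arithmetic mean of the FIRST 2^k
raw frames (prefix averaging): in a real acquisition one would simply stop
scanning after 2^k frames, so prefixes are what a shorter acquisition would
actually deliver.  Level 0 is frame 0 unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .stack_io import ImageStack

__all__ = ["AveragedSeries", "geometric_average"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AveragedSeries:
    """Per-level prefix averages of an xyt stack.

    ``levels[i]`` is the exponent k (so ``2**k`` frames averaged),
    ``images[i]`` the float mean image, and ``last_source_frame[i]`` the
    raw-frame index ``2**k - 1`` of the last frame entering that level.
    """

    levels: np.ndarray
    images: np.ndarray
    last_source_frame: np.ndarray

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.images) or len(self.levels) != len(self.last_source_frame):
            raise ValueError("levels, images and last_source_frame must have equal length")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_averaged(self) -> np.ndarray:
        """Number of frames averaged at each level (2**k)."""
        return 2 ** np.asarray(self.levels)


def geometric_average(stack: ImageStack) -> AveragedSeries:
    """Average the first 2^k frames of ``stack`` for k = 0 .. floor(log2(n)).

    Non-power-of-two stacks are truncated to the largest usable prefix (the
    trailing frames are ignored, with a logged warning).  Averages are kept
    in float; quantization happens only at TIFF export.
    """
    n = stack.n_frames
    K = int(math.floor(math.log2(n)))
    if 2**K > n:  # guard against float log edge cases
        K -= 1
    if 2**K != n:
        logger.warning(
            "stack has %d frames (not a power of two); using the first %d", n, 2**K
        )
    levels = np.arange(K + 1)
    images = np.empty((K + 1, stack.height, stack.width), dtype=np.float64)
    running = np.zeros((stack.height, stack.width), dtype=np.float64)
    count = 0
    for k in range(K + 1):
        target = 2**k
        while count < target:
            running += stack.frames[count]
            count += 1
        images[k] = running / target
    return AveragedSeries(levels=levels, images=images, last_source_frame=2**levels - 1)
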
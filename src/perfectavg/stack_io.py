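"""Multipage grayscale TIFF input/output and deterministic center cropping.

A laser scanning microscope records repeat frames of a single field of view
as an xyt time series; after export each series lives in a multipage TIFF
with one page per time point, in acquisition order.  This module loads such
stacks into float arrays, writes them back at 8-bit, 16-bit or float32
depth, and provides the center crop used for region-of-interest size sweeps.

Only single-channel grayscale stacks are accepted.  Multi-channel or RGB
pages are rejected rather than silently converted: detector data from a
spectral window is single-channel, and a silent channel collapse would
corrupt every downstream intensity statistic.  Proprietary vendor formats
(.lif, .czi, .nd2) are out of scope; convert to TIFF first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "crop_center"]

#: accepted values for the ``bit_depth`` argument of :func:`write_stack`
_INT_DEPTHS = {8: np.uint8, 16: np.uint16}


@dataclass(frozen=True)
class ImageStack:
    """An ordered xyt series of same-shape 2D intensity frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``, float.  Frame index
        ``t = 0`` is the first acquired frame.
    source_bit_depth
        Bit depth of the file the stack was read from (8, 16 or 32), or
        ``None`` for stacks born in memory.
    pixel_size_um
        Optional physical pixel size in micrometers; metadata only.
    """

    frames: np.ndarray
    source_bit_depth: int | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n_frames, height, width) array, got shape {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise ValueError("a stack needs at least one frame")
        if not np.all(np.isfinite(frames)):
            raise ValueError("frames contain non-finite values")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    def frame(self, t: int) -> np.ndarray:
        """Frame at acquisition index ``t`` (0-based)."""
        return self.frames[t]


def read_stack(path: Union[str, Path]) -> ImageStack:
    """Read a multipage grayscale TIFF into an :class:`ImageStack`.

    Page order is preserved: frame ``t`` of the returned stack is page ``t``
    of the file.  Values are converted to float; the original bit depth is
    recorded on the stack.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For zero pages, non-grayscale (RGB / multi-sample) pages,
        inconsistent page shapes, or negative intensities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path} contains zero pages")
        pages = []
        for i, page in enumerate(tif.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(
                    f"page {i} of {path} is not single-channel grayscale "
                    f"(shape {arr.shape}); split channels before analysis"
                )
            pages.append(arr)
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        dtype = pages[0].dtype
    frames = np.stack(pages).astype(np.float64)
    # integer TIFFs hold raw detector counts and must be nonnegative; float
    # TIFFs may be processed/simulated data with small negative excursions
    if dtype.kind in "iu" and np.any(frames < 0):
        raise ValueError(f"{path} contains negative intensities; raw detector counts expected")
    bit_depth = dtype.itemsize * 8
    return ImageStack(frames=frames, source_bit_depth=bit_depth)


def write_stack(
    stack: ImageStack,
    path: Union[str, Path],
    bit_depth: Union[int, str] = "float32",
    clip: bool = True,
) -> Path:
    """Write an :class:`ImageStack` as a multipage grayscale TIFF.

    One page per frame, page order = frame order.  For integer depths the
    values are clipped to the representable range (so averaged intensities
    can never wrap) and rounded half-to-even.  ``bit_depth`` is 8, 16 or
    ``"float32"``.  With ``clip=False``, out-of-range values raise instead.
    """
    path = Path(path)
    data = stack.frames
    if bit_depth in ("float32", 32):
        out = data.astype(np.float32)
    elif bit_depth in _INT_DEPTHS:
        dtype = _INT_DEPTHS[bit_depth]
        vmax = float(np.iinfo(dtype).max)
        if clip:
            data = np.clip(data, 0.0, vmax)
        elif data.min() < 0 or data.max() > vmax:
            raise ValueError(
                f"values outside [0, {vmax:.0f}] cannot be written at {bit_depth}-bit "
                "with clipping disabled"
            )
        out = np.rint(data).astype(dtype)  # np.rint rounds half to even
    else:
        raise ValueError(f"unsupported bit depth {bit_depth!r}; use 8, 16 or 'float32'")
    tifffile.imwrite(path, out, photometric="minisblack")
    return path


def crop_center(stack: ImageStack, side: int) -> ImageStack:
    """Center-crop every frame to a ``side`` x ``side`` square.

    The crop origin is ``floor((dim - side) / 2)`` in each dimension
    (0-based, half-open ranges), so nested crops compose:
    ``crop_center(crop_center(S, a), b) == crop_center(S, b)`` for
    ``b <= a``.  All frames are cropped identically.
    """
    side = int(side)
    if side < 1:
        raise ValueError(f"crop side must be >= 1, got {side}")
    if side > stack.height or side > stack.width:
        raise ValueError(
            f"crop side {side} exceeds frame dimensions "
            f"{stack.height}x{stack.width}"
        )
    r0 = (stack.height - side) // 2
    c0 = (stack.width - side) // 2
    frames = stack.frames[:, r0 : r0 + side, c0 : c0 + side]
    return replace(stack, frames=frames.copy())
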
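"""Acquisition degradation: raster under-sampling, range conversion, patches.

Accelerated photoacoustic raster scanning acquires every s-th scan line in
both axes, so the low-resolution image is a pure decimation of the dense
grid — the retained pixels are the rows and columns whose 0-based index is
congruent to 0 mod s, reducing sampling density by s^2.  No low-pass filter
is applied: the physical scanner simply skips lines.  An optional bicubic
(anti-aliased) mode is provided for conventional SR-benchmark degradation.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import resize

from .image import RANGES, Image

__all__ = [
    "raster_undersample",
    "normalize",
    "extract_patch_pair",
    "bicubic_downsample",
    "bilinear_upsample",
]


def _check_scale(s, h: int, w: int) -> int:
    if not isinstance(s, (int, np.integer)) or isinstance(s, bool):
        raise ValueError("scale factor must be an integer")
    if s < 1:
        raise ValueError("scale factor must be >= 1")
    if s > min(h, w):
        raise ValueError(f"scale {s} exceeds image extent {h}x{w}")
    return int(s)


def raster_undersample(img, s):
    """Keep every s-th row and column (0-based indices ≡ 0 mod s).

    Models the accelerated raster scan: output size is ``ceil(H/s) x
    ceil(W/s)`` and, on s-divisible grids, exactly a fraction ``1/s**2`` of
    the pixels is retained.  No interpolation or filtering is applied.

    Accepts an :class:`~lightsr.image.Image` or a bare array and returns the
    same kind.
    """
    if isinstance(img, Image):
        s = _check_scale(s, img.height, img.width)
        return Image(img.data[::s, ::s], img.range_tag,
                     {**img.meta, "undersample_scale": s})
    arr = np.asarray(img)
    s = _check_scale(s, arr.shape[0], arr.shape[1])
    return arr[::s, ::s]


def normalize(img: Image, target_range: str) -> Image:
    """Exact affine remap of ``img`` onto the ``target_range`` tag.

    The map sends the endpoints of the source range onto the endpoints of
    the target range; composing with the inverse is the identity up to
    floating-point rounding.
    """
    if img.range_tag not in RANGES:
        raise ValueError(f"unknown source range {img.range_tag!r}")
    if target_range not in RANGES:
        raise ValueError(f"unknown target range {target_range!r}")
    (a0, a1), (b0, b1) = RANGES[img.range_tag], RANGES[target_range]
    data = (img.data - a0) * ((b1 - b0) / (a1 - a0)) + b0
    return Image(data, target_range, dict(img.meta))


def extract_patch_pair(hr: Image, patch: int, s: int, rng) -> tuple[Image, Image]:
    """Random patch crop plus its raster-undersampled counterpart.

    Draws a uniformly random ``patch x patch`` crop of ``hr`` (top-left
    offset on the valid grid, deterministic given ``rng``) and returns
    ``(LR, HR)`` with ``LR = raster_undersample(HR, s)``.

    ``rng`` may be a seed or a ``numpy.random.Generator``.
    """
    if patch % s != 0:
        raise ValueError(f"patch size {patch} not divisible by scale {s}")
    h, w = hr.height, hr.width
    if patch > h or patch > w:
        raise ValueError(f"patch {patch} exceeds image extent {h}x{w}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    top = int(gen.integers(0, h - patch + 1))
    left = int(gen.integers(0, w - patch + 1))
    hr_patch = Image(hr.data[top:top + patch, left:left + patch],
                     hr.range_tag, {**hr.meta, "offset": (top, left)})
    return raster_undersample(hr_patch, s), hr_patch


def bicubic_downsample(img, s):
    """Anti-aliased bicubic s-fold down-sampling (alternative degradation)."""
    arr = img.data if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
    s = _check_scale(s, arr.shape[0], arr.shape[1])
    out_shape = (-(-arr.shape[0] // s), -(-arr.shape[1] // s)) + arr.shape[2:]
    out = resize(arr, out_shape, order=3, anti_aliasing=True, mode="reflect")
    if isinstance(img, Image):
        return Image(out, img.range_tag, {**img.meta, "bicubic_scale": s})
    return out


def bilinear_upsample(lr, s):
    """Bilinear interpolation back onto the dense grid (reference baseline).

    Aligned with the decimation phase: LR pixel ``i`` sits at dense-grid
    position ``s*i``, so dense position ``j`` is interpolated at LR
    coordinate ``j/s`` (edge values extended beyond the last sample).
    """
    arr = lr.data if isinstance(lr, Image) else np.asarray(lr, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[..., None]
    h, w, c = arr.shape
    rows = np.arange(h * s, dtype=np.float64) / s
    cols = np.arange(w * s, dtype=np.float64) / s
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    out = np.stack(
        [map_coordinates(arr[..., k], [rr, cc], order=1, mode="nearest")
         for k in range(c)], axis=-1)
    if squeeze:
        out = out[..., 0]
    if isinstance(lr, Image):
        return Image(out, lr.range_tag, dict(lr.meta))
    return out
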
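"""Image container with an explicit intensity-range tag.

Raster-scan photoacoustic images move between three conventions in this
package: raw 8-bit files ([0, 255]), unit-range analysis images ([0, 1]) and
the signed [-1, 1] range the network trains in.  Carrying the declared range
alongside the pixel grid lets every conversion be an exact affine map and
lets shape/range contracts be checked at module boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: declared value ranges, keyed by tag
RANGES: dict[str, tuple[float, float]] = {
    "uint8": (0.0, 255.0),
    "unit": (0.0, 1.0),
    "signed": (-1.0, 1.0),
}


@dataclass
class Image:
    """A 2-D grayscale or 3-channel image with a declared value range.

    Parameters
    ----------
    data : ndarray
        ``(H, W)`` or ``(H, W, C)`` float array, ``C in {1, 3}``.
    range_tag : str
        One of ``"uint8"`` ([0, 255]), ``"unit"`` ([0, 1]) or
        ``"signed"`` ([-1, 1]).
    meta : dict
        Free-form provenance (seed, source bit depth, ...).
    """

    data: np.ndarray
    range_tag: str = "unit"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.range_tag not in RANGES:
            raise ValueError(f"unknown range tag {self.range_tag!r}")
        if self.data.ndim not in (2, 3):
            raise ValueError("image data must be (H, W) or (H, W, C)")
        if self.data.ndim == 3 and self.data.shape[2] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        if self.height < 1 or self.width < 1:
            raise ValueError("image must be at least 1x1")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]

    def copy(self) -> "Image":
        return Image(self.data.copy(), self.range_tag, dict(self.meta))


def as_array(img) -> np.ndarray:
    """Pixel grid of ``img`` whether it is an :class:`Image` or an ndarray."""
    return img.data if isinstance(img, Image) else np.asarray(img, dtype=np.float64)
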
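"""Synthetic vascular / vein phantom generator.

Photoacoustic maximum-amplitude-projection images of microvasculature (and
the topologically similar vein networks of plant leaves) are bright,
curvilinear, fractal-like branching structures on a dark background.  This
module draws such phantoms procedurally so the whole super-resolution
pipeline — degradation, training, re-parameterization, evaluation — can run
and be tested at desk scale without any external acquisition.

The generative model is a recursive random binary tree of smooth random
walks: each vessel is a centerline whose heading performs a bounded random
walk; after a random segment length it splits into two children with
perturbed headings and a width shrunk by a fixed factor per generation.
Centerlines are rendered with a Gaussian cross-section (sigma = half-width/2)
to mimic the point-spread blur of optical-resolution photoacoustic
microscopy, composited by maximum so crossings do not bloom, then additive
Gaussian noise is applied and the image clipped to [0, 1].

The generator is a pure function of (config, seed): identical inputs give
bit-identical images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image import Image

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic vessel phantom distribution.

    Attributes
    ----------
    height, width : int
        Image size in pixels (at least 32 each).
    n_seeds : int
        Number of root vessels.
    branch_depth : int
        Recursion depth of the binary branching tree (0 = unbranched).
    width_range : (float, float)
        Root-vessel half-width in pixels, sampled uniformly; shrinks by
        ``width_decay`` per branch generation.
    intensity_range : (float, float)
        Peak foreground intensity in [0, 1], sampled per root.
    noise_sigma : float
        SD of the additive Gaussian noise, in intensity units (< 1).
    background_level : float
        Dark background intensity in [0, 1].
    width_decay : float
        Multiplicative half-width shrink per branch generation.
    turn_sigma : float
        SD (radians) of the per-step heading perturbation of the walk.
    seed : int
        RNG seed; the phantom is a deterministic function of (config, seed).
    """

    height: int = 256
    width: int = 256
    n_seeds: int = 3
    branch_depth: int = 3
    width_range: tuple[float, float] = (1.0, 3.0)
    intensity_range: tuple[float, float] = (0.6, 1.0)
    noise_sigma: float = 0.02
    background_level: float = 0.05
    width_decay: float = 0.8
    turn_sigma: float = 0.18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom size must be at least 32x32")
        lo, hi = self.width_range
        if not (0.5 <= lo <= hi):
            raise ValueError("width_range must satisfy 0.5 <= min <= max")
        if not (0.0 <= self.noise_sigma < 1.0):
            raise ValueError("noise_sigma must lie in [0, 1)")
        lo, hi = self.intensity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("intensity_range must lie within [0, 1]")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must lie in [0, 1]")
        if self.n_seeds < 0 or self.branch_depth < 0:
            raise ValueError("n_seeds and branch_depth must be non-negative")


def _walk_segment(rng, pos, heading, length, step, turn_sigma):
    """Centerline points of one smooth random-walk segment."""
    pts = []
    n_steps = max(1, int(round(length / step)))
    for _ in range(n_steps):
        heading += rng.normal(0.0, turn_sigma)
        pos = pos + step * np.array([math.sin(heading), math.cos(heading)])
        pts.append((pos[0], pos[1]))
    return pts, pos, heading


def _grow(rng, cfg: PhantomConfig, pos, heading, depth, half_width, seg_len):
    """Recursively grow a binary branching tree of centerline segments.

    Returns a list of ``(points, half_width)`` per segment, root-first;
    child half-widths shrink by ``cfg.width_decay`` per generation.
    """
    step = 1.0
    length = seg_len * rng.uniform(0.7, 1.3)
    pts, end, end_heading = _walk_segment(
        rng, pos, heading, length, step, cfg.turn_sigma)
    segments = [(pts, half_width)]
    if depth > 0:
        split = rng.uniform(0.35, 0.75)
        for sign in (-1.0, 1.0):
            child = end_heading + sign * split * rng.uniform(0.6, 1.4)
            segments += _grow(
                rng, cfg, end.copy(), child, depth - 1,
                half_width * cfg.width_decay, seg_len * 0.85)
    return segments


def _stamp(canvas: np.ndarray, r: float, c: float, sigma: float, peak: float) -> None:
    """Max-composite a Gaussian dot of SD ``sigma`` and height ``peak`` at (r, c)."""
    h, w = canvas.shape
    rad = max(1, int(math.ceil(3.0 * sigma)))
    r0, r1 = int(math.floor(r)) - rad, int(math.floor(r)) + rad + 1
    c0, c1 = int(math.floor(c)) - rad, int(math.floor(c)) + rad + 1
    r0c, r1c = max(r0, 0), min(r1, h)
    c0c, c1c = max(c0, 0), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        return
    rr = np.arange(r0c, r1c, dtype=np.float64) - r
    cc = np.arange(c0c, c1c, dtype=np.float64) - c
    d2 = rr[:, None] ** 2 + cc[None, :] ** 2
    patch = peak * np.exp(-0.5 * d2 / (sigma * sigma))
    np.maximum(canvas[r0c:r1c, c0c:c1c], patch, out=canvas[r0c:r1c, c0c:c1c])


def generate_phantom(config: PhantomConfig, return_centerlines: bool = False):
    """Draw one branching-vessel phantom.

    Parameters
    ----------
    config : PhantomConfig
    return_centerlines : bool
        If true, also return the list of rendered centerlines
        ``[(points, half_width), ...]`` for mask-based testing.

    Returns
    -------
    Image (unit range), or ``(Image, centerlines)``.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    canvas = np.zeros((h, w), dtype=np.float64)
    extent = min(h, w)
    all_segments: list[tuple[list[tuple[float, float]], float]] = []

    for _ in range(config.n_seeds):
        pos = np.array([rng.uniform(0.1 * h, 0.9 * h),
                        rng.uniform(0.1 * w, 0.9 * w)])
        heading = rng.uniform(0.0, 2.0 * math.pi)
        half_width = rng.uniform(*config.width_range)
        peak = rng.uniform(*config.intensity_range)
        seg_len = extent / 4.0
        segments = _grow(rng, config, pos, heading, config.branch_depth,
                         half_width, seg_len)
        for pts, hw in segments:
            sigma = max(hw / 2.0, 0.3)
            for r, c in pts:
                _stamp(canvas, r, c, sigma, peak)
        all_segments += segments

    img = np.maximum(canvas, config.background_level)
    if config.noise_sigma > 0.0:
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    out = Image(img, "unit", {"seed": config.seed})
    if return_centerlines:
        return out, all_segments
    return out


def generate_dataset(n: int, config: PhantomConfig, base_seed: int = 0) -> list[Image]:
    """Generate ``n`` phantoms with per-image seeds ``base_seed + i``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    images = []
    for i in range(n):
        cfg_i = PhantomConfig(**{**config.__dict__, "seed": base_seed + i})
        images.append(generate_phantom(cfg_i))
    return images
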
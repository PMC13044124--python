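"""Full-reference image quality metrics, aggregation, statistics, timing.

RMSE, PSNR and SSIM are computed on images sharing a declared dynamic range
(unit range by default, so MAX_I = L = 1.0; an 8-bit mode uses 255).  SSIM
follows the reference convention — 11x11 Gaussian window with sigma = 1.5,
C1 = (0.01 L)^2, C2 = (0.03 L)^2, mean of the local map over valid window
positions — via scikit-image.

Paired method comparison follows the protocol: Shapiro-Wilk normality test
on the per-image differences (alpha = 0.05), Wilcoxon signed-rank test for
the paired samples, and the paired Cohen's d (mean of differences over
their SD).  Inference timing discards the first measurement to exclude
warm-up effects and reports mean +- SD of the rest.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

from .image import Image, as_array

__all__ = [
    "SSIMParams", "rmse", "psnr", "ssim", "MetricsReport", "evaluate_pairs",
    "ComparisonReport", "paired_compare", "TimingReport", "timing_protocol",
    "PSNR_CAP_DB",
]

#: reported PSNR for identical images, so aggregates stay finite
PSNR_CAP_DB = 100.0


@dataclass
class SSIMParams:
    """Windowed-SSIM parameters (reference convention by default)."""

    win_size: int = 11
    sigma: float = 1.5
    gaussian: bool = True
    data_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03


def _pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, Image) and isinstance(yhat, Image) \
            and y.range_tag != yhat.range_tag:
        raise ValueError("range tags differ")
    a, b = as_array(y), as_array(yhat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return a, b


def rmse(y, yhat) -> float:
    """Root mean square error over all pixels and channels."""
    a, b = _pair(y, yhat)
    d = a - b
    return float(np.sqrt(np.mean(d * d)))


def psnr(y, yhat, max_i: float = 1.0, cap: float = PSNR_CAP_DB) -> float:
    """Peak signal-to-noise ratio, ``20 log10(MAX_I / RMSE)`` in dB.

    Identical images (RMSE = 0) are reported at the finite ``cap`` so that
    mean +- SD aggregation stays defined; callers can detect the case by
    comparing against the cap or checking ``rmse == 0``.
    """
    if max_i <= 0:
        raise ValueError("max_i must be positive")
    r = rmse(y, yhat)
    if r == 0.0:
        return cap
    return 20.0 * math.log10(max_i / r)


def ssim(y, yhat, params: SSIMParams | None = None) -> float:
    """Mean structural similarity over all valid window positions.

    Multi-channel images are scored per channel and averaged.  In [-1, 1];
    exactly 1 iff the images are identical.
    """
    p = params if params is not None else SSIMParams()
    a, b = _pair(y, yhat)
    if min(a.shape[0], a.shape[1]) < p.win_size:
        raise ValueError("image smaller than the SSIM window")
    kwargs = dict(
        win_size=p.win_size, data_range=p.data_range,
        gaussian_weights=p.gaussian, sigma=p.sigma,
        use_sample_covariance=False, K1=p.k1, K2=p.k2,
    )
    if a.ndim == 2:
        return float(structural_similarity(a, b, **kwargs))
    vals = [structural_similarity(a[..., c], b[..., c], **kwargs)
            for c in range(a.shape[2])]
    return float(np.mean(vals))


@dataclass
class MetricsReport:
    """Per-image RMSE/PSNR/SSIM records with mean +- SD aggregates."""

    records: list[dict] = field(default_factory=list)

    def _values(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records], dtype=float)

    def mean(self, key: str) -> float:
        return float(self._values(key).mean())

    def sd(self, key: str) -> float:
        v = self._values(key)
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def to_dict(self) -> dict:
        out = {"n": len(self.records), "records": self.records}
        for key in ("rmse", "psnr", "ssim"):
            out[key] = {"mean": self.mean(key), "sd": self.sd(key)}
        return out

    def __str__(self) -> str:
        return (f"n={len(self.records)}  "
                f"RMSE {self.mean('rmse'):.4f}±{self.sd('rmse'):.4f}  "
                f"PSNR {self.mean('psnr'):.2f}±{self.sd('psnr'):.2f} dB  "
                f"SSIM {self.mean('ssim'):.4f}±{self.sd('ssim'):.4f}")


def evaluate_pairs(pairs, max_i: float = 1.0,
                   ssim_params: SSIMParams | None = None) -> MetricsReport:
    """Score ``(ground_truth, reconstruction)`` pairs into a MetricsReport."""
    if len(pairs) == 0:
        raise ValueError("no image pairs to evaluate")
    report = MetricsReport()
    for i, (y, yhat) in enumerate(pairs):
        r = rmse(y, yhat)
        report.records.append({
            "id": i,
            "rmse": r,
            "psnr": psnr(y, yhat, max_i=max_i),
            "psnr_infinite": r == 0.0,
            "ssim": ssim(y, yhat, ssim_params),
        })
    return report


@dataclass
class ComparisonReport:
    """Paired statistical comparison of two per-image metric series."""

    n: int
    shapiro_p_a: float | None
    shapiro_p_b: float | None
    shapiro_p_diff: float | None
    wilcoxon_p: float | None
    cohens_d: float | None
    selected_test: str
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _shapiro_p(x: np.ndarray) -> float | None:
    if np.ptp(x) == 0:
        return None  # Shapiro-Wilk undefined for constant samples
    return float(stats.shapiro(x).pvalue)


def paired_compare(a, b, alpha: float = 0.05) -> ComparisonReport:
    """Protocolized paired comparison of two methods' per-image scores.

    Shapiro-Wilk on the paired differences decides which test the protocol
    selects (Wilcoxon signed-rank when non-normal); the Wilcoxon p and the
    paired Cohen's d ``mean(a - b) / SD(a - b)`` are reported regardless,
    with degenerate cases (all-zero or zero-variance differences) flagged
    instead of raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D sequences")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    flags: list[str] = []

    sd_d = float(d.std(ddof=1))
    # constant differences (up to rounding) make both tests degenerate
    constant = sd_d <= 1e-12 * max(1.0, float(np.abs(d).max()))
    if np.all(d == 0):
        flags.append("all differences zero; Wilcoxon degenerate")
        wilcoxon_p = None
        cohens_d = 0.0
    else:
        wilcoxon_p = float(stats.wilcoxon(a, b).pvalue)
        if constant:
            flags.append("zero-variance differences; Cohen's d undefined")
            cohens_d = None
        else:
            cohens_d = float(d.mean() / sd_d)

    p_diff = _shapiro_p(d)
    selected = "wilcoxon" if (p_diff is None or p_diff < alpha) else "paired-t"
    return ComparisonReport(
        n=n,
        shapiro_p_a=_shapiro_p(a),
        shapiro_p_b=_shapiro_p(b),
        shapiro_p_diff=p_diff,
        wilcoxon_p=wilcoxon_p,
        cohens_d=cohens_d,
        selected_test=selected,
        flags=flags,
    )


@dataclass
class TimingReport:
    mean_s: float
    sd_s: float
    times_s: list[float]
    n_discarded: int
    hardware: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def timing_protocol(model, inputs, timer=None, hardware: str | None = None
                    ) -> TimingReport:
    """Sequential inference timing, first measurement discarded (warm-up).

    ``timer`` is a monotonic clock called before and after each inference
    (injectable for testing); the report aggregates mean +- SD (n-1
    denominator) over the retained measurements.
    """
    if len(inputs) < 3:
        raise ValueError("need at least 3 inputs for a timing estimate")
    clock = timer if timer is not None else time.perf_counter
    durations = []
    for x in inputs:
        t0 = clock()
        model.predict(as_array(x))
        t1 = clock()
        durations.append(t1 - t0)
    kept = durations[1:]
    mean = float(np.mean(kept))
    sd = float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0
    if hardware is None:
        import platform

        hardware = f"{platform.machine()} / {platform.processor() or 'cpu'}"
    return TimingReport(mean, sd, kept, 1, hardware)
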
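"""Quality metrics against independent oracles; statistics; timing protocol."""

import math

import numpy as np
import pytest

from lightsr import (SSIMParams, paired_compare, psnr, rmse, ssim,
                     timing_protocol)
from lightsr.metrics import PSNR_CAP_DB, evaluate_pairs


def brute_force_ssim(x, y, win=11, sigma=1.5, L=1.0, k1=0.01, k2=0.03):
    """Independent sliding-window SSIM: explicit loop over valid positions."""
    r = win // 2
    i = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-(i ** 2) / (2 * sigma ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    h, wd = x.shape
    vals = []
    for a in range(r, h - r):
        for b in range(r, wd - r):
            px = x[a - r:a + r + 1, b - r:b + r + 1]
            py = y[a - r:a + r + 1, b - r:b + r + 1]
            mx, my = np.sum(w * px), np.sum(w * py)
            vx = np.sum(w * (px - mx) ** 2)
            vy = np.sum(w * (py - my) ** 2)
            vxy = np.sum(w * (px - mx) * (py - my))
            vals.append(((2 * mx * my + c1) * (2 * vxy + c2))
                        / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


class TestRMSE:
    def test_identical_and_constant_difference(self, rng):
        x = rng.uniform(size=(8, 8))
        assert rmse(x, x) == 0.0
        assert rmse(x, x + 0.5) == pytest.approx(0.5, abs=1e-15)

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            a = rng.uniform(size=(6, 7))
            b = rng.uniform(size=(6, 7))
            brute = math.sqrt(sum((p - q) ** 2 for p, q in
                                  zip(a.ravel(), b.ravel())) / a.size)
            assert rmse(a, b) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            rmse(rng.uniform(size=(4, 4)), rng.uniform(size=(4, 5)))


class TestPSNR:
    def test_zero_db_when_rmse_equals_peak(self, rng):
        x = np.zeros((4, 4))
        assert psnr(x, x + 1.0, max_i=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_difference_closed_form(self):
        x = np.zeros((16, 16))
        assert psnr(x, x + 0.5, max_i=1.0) == pytest.approx(
            20 * math.log10(2), abs=1e-10)

    def test_identical_images_capped(self, rng):
        x = rng.uniform(size=(4, 4))
        assert psnr(x, x) == PSNR_CAP_DB

    def test_consistency_with_rmse(self, rng):
        a, b = rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8))
        want = 20 * math.log10(1.0) - 20 * math.log10(rmse(a, b))
        assert psnr(a, b) == pytest.approx(want, abs=1e-12)


class TestSSIM:
    def test_identical_images_give_exactly_one(self, rng):
        x = rng.uniform(size=(16, 16))
        assert ssim(x, x) == 1.0

    def test_constant_images_closed_form(self):
        x = np.zeros((16, 16))
        y = np.ones((16, 16))
        c1 = 1e-4
        assert ssim(x, y) == pytest.approx(c1 / (1 + c1), rel=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            a = rng.uniform(size=(20, 20))
            b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
            assert ssim(a, b) == pytest.approx(brute_force_ssim(a, b),
                                               abs=1e-6)

    def test_symmetry_and_bounds(self, rng):
        a, b = rng.uniform(size=(16, 16)), rng.uniform(size=(16, 16))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)
        assert -1.0 <= ssim(a, b) <= 1.0

    def test_window_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.uniform(size=(8, 8)), rng.uniform(size=(8, 8)))

    def test_eight_bit_range_mode(self, rng):
        a = rng.uniform(size=(16, 16))
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        unit = ssim(a, b)
        eight = ssim(a * 255, b * 255, SSIMParams(data_range=255.0))
        assert eight == pytest.approx(unit, abs=1e-9)


class TestAggregation:
    def test_leave_one_out_mean_identity(self, rng):
        pairs = [(rng.uniform(size=(16, 16)),
                  rng.uniform(size=(16, 16))) for _ in range(6)]
        full = evaluate_pairs(pairs)
        reduced = evaluate_pairs(pairs[:-1])
        vals = [r["psnr"] for r in full.records]
        loo = (sum(vals) - vals[-1]) / (len(vals) - 1)
        assert reduced.mean("psnr") == pytest.approx(loo, abs=1e-12)

    def test_sd_uses_n_minus_one(self, rng):
        pairs = [(rng.uniform(size=(16, 16)),
                  rng.uniform(size=(16, 16))) for _ in range(4)]
        rep = evaluate_pairs(pairs)
        vals = np.array([r["rmse"] for r in rep.records])
        assert rep.sd("rmse") == pytest.approx(vals.std(ddof=1), abs=1e-15)


class TestPairedCompare:
    def test_identical_series_degenerate(self, rng):
        a = rng.uniform(size=10)
        rep = paired_compare(a, a.copy())
        assert rep.cohens_d == 0.0
        assert rep.wilcoxon_p is None
        assert any("zero" in f for f in rep.flags)

    def test_constant_shift_flags_undefined_d(self, rng):
        a = rng.uniform(size=10)
        rep = paired_compare(a, a + 1.0)
        assert rep.cohens_d is None
        assert any("undefined" in f for f in rep.flags)

    def test_shifted_normals_against_independent_oracles(self):
        pg = pytest.importorskip("pingouin")
        gen = np.random.default_rng(0)
        a = gen.normal(1.0, 1.0, 30)
        b = gen.normal(0.0, 1.0, 30)
        rep = paired_compare(a, b)
        assert rep.wilcoxon_p < 0.05
        ref_p = float(pg.wilcoxon(a, b)["p_val"].iloc[0])
        assert rep.wilcoxon_p == pytest.approx(ref_p, rel=0.10)
        # difference-score d equals the paired t statistic over sqrt(n)
        t = float(pg.ttest(a, b, paired=True)["T"].iloc[0])
        assert rep.cohens_d == pytest.approx(t / math.sqrt(30), rel=0.10)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_compare(rng.uniform(size=6), rng.uniform(size=7))


class _InstantModel:
    def __init__(self):
        from lightsr import ModelConfig

        self.config = ModelConfig(scale=2, in_channels=1)

    def predict(self, lr):
        return lr


class TestTimingProtocol:
    def test_fake_timer_discards_first_measurement(self, rng):
        # durations per call: 10, 1, 1, 1 -> retained mean 1.0, SD 0.0
        ticks = iter([0.0, 10.0, 10.0, 11.0, 11.0, 12.0, 12.0, 13.0])
        rep = timing_protocol(_InstantModel(),
                              [rng.uniform(size=(8, 8)) for _ in range(4)],
                              timer=lambda: next(ticks))
        assert rep.mean_s == pytest.approx(1.0)
        assert rep.sd_s == 0.0
        assert rep.n_discarded == 1

    def test_retains_n_minus_one_measurements(self, rng):
        rep = timing_protocol(_InstantModel(),
                              [rng.uniform(size=(8, 8)) for _ in range(6)])
        assert len(rep.times_s) == 5

    def test_too_few_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            timing_protocol(_InstantModel(),
                            [rng.uniform(size=(8, 8)) for _ in range(2)])
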
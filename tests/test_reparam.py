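"""Branch-fusion algebra: batch-norm folding, kernel lifting, equivalence."""

import numpy as np
import pytest

from lightsr import LightRepViTSR, ModelConfig, TrainConfig, train
from lightsr.model import TokenMixer
from lightsr.nn import BatchNorm2d, Conv2d
from lightsr.phantom import PhantomConfig, generate_dataset
from lightsr.reparam import (fold_bn, fuse_token_mixer, identity_to_dw3x3,
                             lift_1x1_to_3x3, reparameterize_model)


def _identity_bn(channels):
    bn = BatchNorm2d(channels, eps=0.0)
    return bn


class TestFoldBn:
    def test_identity_bn_returns_same_kernel_zero_bias(self, rng):
        conv = Conv2d(3, 3, 3, groups=3, bias=False, rng=rng)
        fused = fold_bn(conv, _identity_bn(3))
        assert np.array_equal(fused.weight.data, conv.weight.data)
        assert np.array_equal(fused.bias.data, np.zeros(3))

    def test_scalar_algebraic_expansion(self):
        # w=2 (no bias), gamma=3, beta=1, mu=4, var=0.25:
        # 3*(2x-4)/0.5 + 1 = 12x - 23
        conv = Conv2d(1, 1, 1, bias=False)
        conv.weight.data[...] = 2.0
        bn = BatchNorm2d(1, eps=0.0)
        bn.gamma.data[:] = 3.0
        bn.beta.data[:] = 1.0
        bn.running_mean[:] = 4.0
        bn.running_var[:] = 0.25
        fused = fold_bn(conv, bn)
        assert fused.weight.data.ravel()[0] == pytest.approx(12.0)
        assert fused.bias.data[0] == pytest.approx(-23.0)

    def test_forward_equivalence_on_random_inputs(self, rng):
        conv = Conv2d(4, 4, 3, groups=4, bias=True, rng=rng)
        bn = BatchNorm2d(4)
        bn.gamma.data[:] = rng.uniform(0.5, 2.0, 4)
        bn.beta.data[:] = rng.normal(size=4)
        bn.running_mean[:] = rng.normal(size=4)
        bn.running_var[:] = rng.uniform(0.1, 2.0, 4)
        fused = fold_bn(conv, bn)
        for _ in range(100):
            x = rng.normal(size=(1, 4, 6, 6))
            want = bn.forward(conv.forward(x), training=False)
            assert np.allclose(fused.forward(x), want, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            fold_bn(Conv2d(2, 2, 3, rng=rng), BatchNorm2d(3))

    def test_nonpositive_variance_rejected(self, rng):
        bn = BatchNorm2d(2, eps=0.0)
        bn.running_var[:] = 0.0
        with pytest.raises(ValueError):
            fold_bn(Conv2d(2, 2, 3, rng=rng), bn)


class TestLift1x1:
    def test_scalar_center_embedding(self):
        k = Conv2d(1, 1, 1, bias=False)
        k.weight.data[...] = 5.0
        lifted = lift_1x1_to_3x3(k)
        assert np.array_equal(lifted.weight.data[0, 0],
                              [[0, 0, 0], [0, 5, 0], [0, 0, 0]])

    def test_zero_kernel_stays_zero(self):
        lifted = lift_1x1_to_3x3(Conv2d(2, 2, 1, groups=2, bias=False))
        assert np.all(lifted.weight.data == 0)

    def test_forward_identical_to_1x1(self, rng):
        k = Conv2d(3, 3, 1, groups=3, bias=True, rng=rng)
        lifted = lift_1x1_to_3x3(k)
        x = rng.normal(size=(2, 3, 5, 5))
        assert np.array_equal(k.forward(x), lifted.forward(x))

    def test_non_1x1_rejected(self, rng):
        with pytest.raises(ValueError):
            lift_1x1_to_3x3(Conv2d(2, 2, 3, rng=rng))


class TestIdentityKernel:
    def test_structure(self):
        k = identity_to_dw3x3(2)
        for c in range(2):
            assert np.array_equal(k.weight.data[c, 0],
                                  [[0, 0, 0], [0, 1, 0], [0, 0, 0]])
        assert np.all(k.bias.data == 0)

    def test_acts_as_identity(self, rng):
        x = rng.normal(size=(1, 2, 7, 7))
        assert np.array_equal(identity_to_dw3x3(2).forward(x), x)

    def test_additivity_with_another_kernel(self, rng):
        other = Conv2d(2, 2, 3, groups=2, bias=False, rng=rng)
        combo = Conv2d(2, 2, 3, groups=2, bias=False)
        combo.weight.data[...] = (other.weight.data
                                  + identity_to_dw3x3(2).weight.data)
        x = rng.normal(size=(1, 2, 6, 6))
        assert np.allclose(combo.forward(x), other.forward(x) + x, atol=1e-12)

    def test_invalid_channel_count(self):
        with pytest.raises(ValueError):
            identity_to_dw3x3(0)


class TestFuseTokenMixer:
    def test_zero_branches_fuse_to_identity_kernel(self):
        tm = TokenMixer(3, rng=None, name="tm")
        tm.bn3.eps = tm.bn1.eps = 0.0
        fused = fuse_token_mixer(tm)
        assert np.array_equal(fused.weight.data,
                              identity_to_dw3x3(3).weight.data)
        assert np.all(fused.bias.data == 0)

    def test_delta_branch_weights_sum_at_center(self):
        tm = TokenMixer(1, rng=None, name="tm")
        tm.bn3.eps = tm.bn1.eps = 0.0
        tm.dw3.weight.data[:, 0, 1, 1] = 2.0
        tm.dw1.weight.data[:, 0, 0, 0] = 3.0
        fused = fuse_token_mixer(tm)
        assert fused.weight.data[0, 0, 1, 1] == pytest.approx(6.0)

    def test_equivalence_after_bn_statistics_update(self, rng):
        tm = TokenMixer(4, rng=rng, name="tm")
        for _ in range(10):  # populate running statistics
            tm.forward(rng.normal(1.0, 2.0, size=(2, 4, 8, 8)), training=True)
        fused = fuse_token_mixer(tm)
        for _ in range(100):
            x = rng.normal(size=(1, 4, 8, 8))
            assert np.max(np.abs(fused.forward(x)
                                 - tm.forward(x, training=False))) < 1e-10


class TestReparameterizeModel:
    def test_fresh_model_equivalence_is_float64_exact(self, tiny_model, rng):
        deployed = reparameterize_model(tiny_model)
        x = rng.uniform(-1, 1, size=(2, 1, 12, 12))
        err = np.max(np.abs(tiny_model.forward(x) - deployed.forward(x)))
        assert err < 1e-12

    def test_trained_model_equivalence(self, rng):
        phantoms = generate_dataset(
            10, PhantomConfig(height=32, width=32, n_seeds=2, branch_depth=2),
            base_seed=1)
        model = LightRepViTSR(ModelConfig(scale=2, in_channels=1,
                                          stem_channels=8, n_blocks=3),
                              init_seed=4)
        train(model, phantoms, TrainConfig(epochs=2, batch_size=5,
                                           patch=None, seed=0))
        deployed = reparameterize_model(model)
        worst = 0.0
        for _ in range(20):
            x = rng.uniform(-1, 1, size=(1, 1, 16, 16))
            worst = max(worst, float(np.max(np.abs(
                model.forward(x) - deployed.forward(x)))))
        assert worst < 1e-10

    def test_deploy_count_strictly_smaller(self, tiny_model):
        deployed = reparameterize_model(tiny_model)
        assert deployed.count_parameters() < tiny_model.count_parameters()

    def test_redeployment_rejected(self, tiny_model):
        deployed = reparameterize_model(tiny_model)
        with pytest.raises(ValueError):
            reparameterize_model(deployed)

    def test_fusion_order_invariance(self, rng):
        """Summing folded branches is commutative up to 1-ulp effects."""
        tm = TokenMixer(3, rng=rng, name="tm")
        b3 = fold_bn(tm.dw3, tm.bn3)
        b1 = lift_1x1_to_3x3(fold_bn(tm.dw1, tm.bn1))
        bi = identity_to_dw3x3(3)
        w_fwd = b3.weight.data + b1.weight.data + bi.weight.data
        w_rev = bi.weight.data + b1.weight.data + b3.weight.data
        assert np.allclose(w_fwd, w_rev, atol=1e-15)
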
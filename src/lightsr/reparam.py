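"""Structural re-parameterization: branch fusion for deployment.

During training each token mixer holds three parallel branches — a 3x3
depthwise convolution with batch norm, a 1x1 depthwise convolution with
batch norm, and an identity shortcut.  Because convolution, batch
normalization (in inference mode) and addition are all affine in the input,
the three branches sum to a single affine map, representable as ONE biased
3x3 depthwise convolution:

* batch-norm folding:  BN(conv(x)) = conv'(x) with
  ``W' = W * gamma / sqrt(var + eps)`` (per output channel) and
  ``b' = beta + (b - mu) * gamma / sqrt(var + eps)``;
* a 1x1 kernel embeds into a 3x3 kernel with the weight at the center;
* the identity is a 3x3 depthwise kernel with 1 at each channel's center;
* parallel branches add kernel-wise and bias-wise.

The fusion is algebraically exact: any observed train/deploy output
difference is pure floating-point rounding and shrinks with precision.
"""

from __future__ import annotations

import copy

import numpy as np

from .nn import BatchNorm2d, Conv2d
from .model import FusedTokenMixer, LightRepViTSR, TokenMixer

__all__ = [
    "fold_bn", "lift_1x1_to_3x3", "identity_to_dw3x3",
    "fuse_token_mixer", "reparameterize_model",
]


def fold_bn(conv: Conv2d, bn: BatchNorm2d) -> Conv2d:
    """Absorb inference-mode batch-norm statistics into the convolution.

    Returns a new biased convolution whose forward equals ``bn(conv(.))``
    exactly in real arithmetic.
    """
    if bn.channels != conv.out_ch:
        raise ValueError(
            f"channel mismatch: conv out {conv.out_ch} vs bn {bn.channels}")
    var_eps = bn.running_var + bn.eps
    if np.any(var_eps <= 0):
        raise ValueError("batch-norm variance + eps must be positive")
    scale = bn.gamma.data / np.sqrt(var_eps)
    fused = Conv2d(conv.in_ch, conv.out_ch, conv.kernel, groups=conv.groups,
                   bias=True, name=conv.weight.name + ".folded")
    fused.weight.data[...] = conv.weight.data * scale[:, None, None, None]
    b_conv = conv.bias.data if conv.bias is not None else 0.0
    fused.bias.data[...] = bn.beta.data + (b_conv - bn.running_mean) * scale
    return fused


def lift_1x1_to_3x3(k: Conv2d) -> Conv2d:
    """Embed a 1x1 kernel at the center of a zero 3x3 kernel (same bias).

    Under 'same' padding the lifted convolution computes identical outputs.
    """
    if k.kernel != 1:
        raise ValueError("lift_1x1_to_3x3 expects a 1x1 convolution")
    out = Conv2d(k.in_ch, k.out_ch, 3, groups=k.groups,
                 bias=k.bias is not None, name=k.weight.name + ".lifted")
    out.weight.data[:, :, 1, 1] = k.weight.data[:, :, 0, 0]
    if k.bias is not None:
        out.bias.data[...] = k.bias.data
    return out


def identity_to_dw3x3(channels: int) -> Conv2d:
    """Depthwise 3x3 convolution acting as the identity on any feature map."""
    if channels < 1:
        raise ValueError("channel count must be >= 1")
    k = Conv2d(channels, channels, 3, groups=channels, bias=True,
               name="identity3x3")
    k.weight.data[:, 0, 1, 1] = 1.0
    return k


def fuse_token_mixer(tm: TokenMixer) -> Conv2d:
    """Collapse the three training branches into one biased DW 3x3 convolution.

    The fused kernel/bias is the elementwise sum of ``fold_bn(dw3x3, bn3)``,
    ``lift_1x1_to_3x3(fold_bn(dw1x1, bn1))`` and the identity kernel.
    """
    c = tm.channels
    b3 = fold_bn(tm.dw3, tm.bn3)
    b1 = lift_1x1_to_3x3(fold_bn(tm.dw1, tm.bn1))
    bi = identity_to_dw3x3(c)
    fused = Conv2d(c, c, 3, groups=c, bias=True, name="fused_tm")
    fused.weight.data[...] = b3.weight.data + b1.weight.data + bi.weight.data
    fused.bias.data[...] = b3.bias.data + b1.bias.data + bi.bias.data
    return fused


def reparameterize_model(model: LightRepViTSR) -> LightRepViTSR:
    """Return the deploy-form model with every token mixer fused.

    All other layers (stem, channel mixers, SE gates, up-sampler) are copied
    unchanged; outputs match the training form up to floating-point rounding
    and the parameter count is strictly smaller.  Re-parameterizing an
    already-deployed model is rejected.
    """
    if model.mode != "train":
        raise ValueError("model is already in deploy form")
    deployed = copy.deepcopy(model)
    deployed.mode = "deploy"
    for i, (src, dst) in enumerate(zip(model.blocks, deployed.blocks)):
        fused = FusedTokenMixer(src.token_mixer.channels, name=f"block{i}.fused")
        fused.conv = fuse_token_mixer(src.token_mixer)
        fused.conv.weight.name = f"block{i}.fused.weight"
        fused.conv.bias.name = f"block{i}.fused.bias"
        dst.token_mixer = fused
    return deployed
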
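"""The Light-RepViTSR network.

An ultra-lightweight single-image super-resolution network for raster-scan
photoacoustic images, built from four pieces:

* a minimalist stem — one 3x3 convolution lifting the input to C feature
  channels (C = 16 by default) at the input resolution;
* a chain of identity-mapping RepViT blocks (3 by default), each separating
  spatial *token mixing* (a three-branch depthwise module: 3x3 DW conv + BN,
  1x1 DW conv + BN, identity) from *channel mixing* (a residual two-layer
  1x1-conv MLP with GELU, expanding C -> expansion*C -> C);
* a global residual adding the stem features back after the block chain, so
  the blocks learn the high-frequency residue;
* a unified up-sampler — 3x3 conv expanding to out_channels*s^2 channels,
  one pixel-shuffle by the scale factor s, a final 3x3 conv — followed by a
  tanh that constrains outputs to [-1, 1].

The three token-mixer branches exist only during training: structural
re-parameterization (:mod:`lightsr.reparam`) collapses them into a single
3x3 depthwise convolution for deployment with provably identical outputs.

The model object follows the fit/results idiom: :meth:`LightRepViTSR.fit`
trains on a list of high-resolution images and returns a
:class:`~lightsr.train.SRFitResults` carrying the history and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, GELU, PixelShuffle, SqueezeExcite,
                 Tanh, Parameter)

__all__ = ["ModelConfig", "LightRepViTSR", "build_model"]

_ALLOWED_SCALES = (2, 4, 8)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    scale : up-sampling factor, one of {2, 4, 8}
    in_channels : input channels (3 for RGB, 1 for single-channel maps)
    stem_channels : feature width C of the stem and blocks (default 16)
    n_blocks : number of RepViT blocks (default 3)
    expansion : channel-mixer expansion ratio (default 2, i.e. C -> 2C)
    use_se : insert a squeeze-and-excitation gate after each token mixer
        (ablation variant; the reference design omits it)
    se_reduction : SE bottleneck ratio (default 4)
    use_residual : global stem-to-output residual (ablation switch)
    out_channels : output channels (defaults to ``in_channels``)
    init : weight init scheme, "kaiming_uniform" (fan-in, a=sqrt(5); keeps
        the tanh tail responsive at depth) or "kaiming_normal" (fan-in,
        ReLU gain)
    """

    scale: int = 2
    in_channels: int = 3
    stem_channels: int = 16
    n_blocks: int = 3
    expansion: int = 2
    use_se: bool = False
    se_reduction: int = 4
    use_residual: bool = True
    out_channels: int | None = None
    init: str = "kaiming_uniform"

    def __post_init__(self) -> None:
        if self.scale not in _ALLOWED_SCALES:
            raise ValueError(f"scale must be one of {_ALLOWED_SCALES}")
        if self.stem_channels < 1 or self.n_blocks < 1 or self.expansion < 1:
            raise ValueError("stem_channels, n_blocks, expansion must be >= 1")
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 or 3")
        if self.out_channels is None:
            self.out_channels = self.in_channels

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class TokenMixer:
    """Training-form RepVGGDW module: BN(DW3x3(x)) + BN(DW1x1(x)) + x."""

    def __init__(self, channels: int, rng, name: str, init: str = "kaiming_uniform"):
        self.channels = channels
        self.dw3 = Conv2d(channels, channels, 3, groups=channels, bias=False,
                          rng=rng, init=init, name=f"{name}.dw3")
        self.bn3 = BatchNorm2d(channels, name=f"{name}.bn3")
        self.dw1 = Conv2d(channels, channels, 1, groups=channels, bias=False,
                          rng=rng, init=init, name=f"{name}.dw1")
        self.bn1 = BatchNorm2d(channels, name=f"{name}.bn1")

    def params(self):
        return (self.dw3.params() + self.bn3.params()
                + self.dw1.params() + self.bn1.params())

    def forward(self, x, training):
        return (self.bn3.forward(self.dw3.forward(x), training)
                + self.bn1.forward(self.dw1.forward(x), training)
                + x)

    def backward(self, gy):
        return (self.dw3.backward(self.bn3.backward(gy))
                + self.dw1.backward(self.bn1.backward(gy))
                + gy)


class FusedTokenMixer:
    """Deploy-form token mixer: a single biased 3x3 depthwise convolution."""

    def __init__(self, channels: int, name: str = "fused"):
        self.channels = channels
        self.conv = Conv2d(channels, channels, 3, groups=channels, bias=True,
                           name=name)

    def params(self):
        return self.conv.params()

    def forward(self, x, training=False):
        return self.conv.forward(x)

    def backward(self, gy):
        return self.conv.backward(gy)


class ChannelMixer:
    """Residual pointwise MLP: x + Conv1x1(GELU(Conv1x1(x))), C -> eC -> C."""

    def __init__(self, channels: int, expansion: int, rng, name: str,
                 init: str = "kaiming_uniform"):
        hidden = channels * expansion
        self.expand = Conv2d(channels, hidden, 1, rng=rng, init=init,
                             name=f"{name}.expand")
        self.gelu = GELU()
        self.project = Conv2d(hidden, channels, 1, rng=rng, init=init,
                              name=f"{name}.project")

    def params(self):
        return self.expand.params() + self.project.params()

    def forward(self, x, training=False):
        return x + self.project.forward(
            self.gelu.forward(self.expand.forward(x)))

    def backward(self, gy):
        return gy + self.expand.backward(
            self.gelu.backward(self.project.backward(gy)))


class RepViTBlock:
    """Identity-mapping RepViT block: token mixer (+ optional SE), channel mixer."""

    def __init__(self, channels: int, expansion: int, use_se: bool,
                 se_reduction: int, rng, name: str,
                 init: str = "kaiming_uniform"):
        self.token_mixer = TokenMixer(channels, rng, f"{name}.tm", init)
        self.se = (SqueezeExcite(channels, se_reduction, rng, init, f"{name}.se")
                   if use_se else None)
        self.channel_mixer = ChannelMixer(channels, expansion, rng,
                                          f"{name}.cm", init)

    def params(self):
        p = self.token_mixer.params()
        if self.se is not None:
            p += self.se.params()
        return p + self.channel_mixer.params()

    def forward(self, x, training):
        y = self.token_mixer.forward(x, training)
        if self.se is not None:
            y = self.se.forward(y)
        return self.channel_mixer.forward(y, training)

    def backward(self, gy):
        g = self.channel_mixer.backward(gy)
        if self.se is not None:
            g = self.se.backward(g)
        return self.token_mixer.backward(g)


class LightRepViTSR:
    """The super-resolution model (training or deployed form).

    Parameters
    ----------
    config : ModelConfig
    init_seed : int
        Seed for the Kaiming weight initialization (scheme set by
        ``config.init``); two builds with the same seed have identical
        parameters.
    """

    def __init__(self, config: ModelConfig, init_seed: int = 0):
        self.config = config
        self.init_seed = init_seed
        self.mode = "train"
        rng = np.random.default_rng(init_seed)
        c, cin, cout, s = (config.stem_channels, config.in_channels,
                           config.out_channels, config.scale)
        self.stem = Conv2d(cin, c, 3, rng=rng, init=config.init, name="stem")
        self.blocks = [
            RepViTBlock(c, config.expansion, config.use_se,
                        config.se_reduction, rng, f"block{i}", config.init)
            for i in range(config.n_blocks)
        ]
        self.up_expand = Conv2d(c, cout * s * s, 3, rng=rng, init=config.init,
                                name="up.expand")
        self.shuffle = PixelShuffle(s)
        self.up_final = Conv2d(cout, cout, 3, rng=rng, init=config.init,
                               name="up.final")
        self.tanh = Tanh()

    # ------------------------------------------------------------------ core
    def parameters(self) -> list[Parameter]:
        p = self.stem.params()
        for b in self.blocks:
            p += b.params()
        return p + self.up_expand.params() + self.up_final.params()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map an LR batch (N, C, H, W) in [-1, 1] to an SR batch (N, C, sH, sW).

        Output values lie in [-1, 1] (tanh applied last).
        """
        x = np.asarray(x)
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float64)
        if x.ndim != 4:
            raise ValueError("input must be a (N, C, H, W) batch")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.shape[1]}")
        f0 = self.stem.forward(x)
        f = f0
        for b in self.blocks:
            f = b.forward(f, training)
        if self.config.use_residual:
            f = f + f0
        u = self.up_expand.forward(f)
        u = self.shuffle.forward(u)
        u = self.up_final.forward(u)
        return self.tanh.forward(u)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Back-propagate a loss gradient; accumulates into parameter grads."""
        g = self.tanh.backward(gy)
        g = self.up_final.backward(g)
        g = self.shuffle.backward(g)
        g = self.up_expand.backward(g)
        g_res = g if self.config.use_residual else None
        for b in reversed(self.blocks):
            g = b.backward(g)
        if g_res is not None:
            g = g + g_res
        return self.stem.backward(g)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def count_parameters(self, mode: str | None = None) -> int:
        """Number of learnable scalars (BN running statistics never counted).

        ``mode="deploy"`` on a training-form model reports the count the
        fused network will have: each token mixer's two branch kernels and
        two batch norms collapse into one biased 3x3 depthwise convolution.
        """
        total = sum(p.size for p in self.parameters())
        if mode is None or mode == self.mode:
            return total
        if self.mode == "train" and mode == "deploy":
            c = self.config.stem_channels
            for b in self.blocks:
                total -= sum(p.size for p in b.token_mixer.params())
                total += 9 * c + c  # fused DW3x3 weight + bias
            return total
        raise ValueError(f"cannot report {mode!r} count for a {self.mode} model")

    # ------------------------------------------------------------ convenience
    def predict(self, lr_unit: np.ndarray) -> np.ndarray:
        """Super-resolve one unit-range image (H, W) or (H, W, C).

        Handles the [0,1] -> [-1,1] -> [0,1] round trip around the network.
        """
        from .image import Image, as_array

        arr = as_array(lr_unit)
        squeeze = arr.ndim == 2
        if squeeze:
            arr = arr[..., None]
        x = (arr * 2.0 - 1.0).transpose(2, 0, 1)[None]
        y = self.forward(x, training=False)[0].transpose(1, 2, 0)
        out = np.clip((y + 1.0) / 2.0, 0.0, 1.0)
        return out[..., 0] if squeeze else out

    def fit(self, hr_images, train_config=None):
        """Train on high-resolution images; returns :class:`SRFitResults`.

        ``hr_images`` is a list of unit-range images (`Image` or arrays);
        low-resolution inputs are produced internally by raster
        under-sampling at the model's scale.
        """
        from .train import TrainConfig, train

        cfg = train_config if train_config is not None else TrainConfig()
        return train(self, hr_images, cfg)

    def reparameterize(self):
        """Deploy-form copy with every token mixer fused (see :mod:`reparam`)."""
        from .reparam import reparameterize_model

        return reparameterize_model(self)

    def astype(self, dtype) -> "LightRepViTSR":
        """Cast all parameters and BN statistics in place (e.g. float32).

        NumPy's promotion rules then keep the whole forward pass in that
        precision, which is how the train/deploy equivalence is verified at
        reduced precision.
        """
        for p in self.parameters():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)
        for b in self.blocks:
            tm = b.token_mixer
            if isinstance(tm, TokenMixer):
                for bn in (tm.bn3, tm.bn1):
                    bn.running_mean = bn.running_mean.astype(dtype)
                    bn.running_var = bn.running_var.astype(dtype)
        return self

    # ----------------------------------------------------------------- state
    def state_dict(self) -> dict:
        d = {p.name: p.data for p in self.parameters()}
        if self.mode == "train":
            for i, b in enumerate(self.blocks):
                tm = b.token_mixer
                for tag, bn in (("bn3", tm.bn3), ("bn1", tm.bn1)):
                    d[f"block{i}.tm.{tag}.running_mean"] = bn.running_mean
                    d[f"block{i}.tm.{tag}.running_var"] = bn.running_var
        return d

    def load_state_dict(self, d: dict) -> None:
        for p in self.parameters():
            p.data[...] = d[p.name]
        if self.mode == "train":
            for i, b in enumerate(self.blocks):
                tm = b.token_mixer
                for tag, bn in (("bn3", tm.bn3), ("bn1", tm.bn1)):
                    bn.running_mean[...] = d[f"block{i}.tm.{tag}.running_mean"]
                    bn.running_var[...] = d[f"block{i}.tm.{tag}.running_var"]


def build_model(config: ModelConfig, init_seed: int = 0) -> LightRepViTSR:
    """Construct a training-form model (functional alias for the class)."""
    return LightRepViTSR(config, init_seed)
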
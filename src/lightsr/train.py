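"""Training pipeline: stabilized MSE loss, AdamW + cosine schedule, patches.

Two regimes mirror the acquisition study design: moderate under-sampling
(x2/x4) trains on randomly cropped patches from each image, extreme
under-sampling (x8) on full images so global context survives the
information loss.  Each optimizer step samples high-resolution patches,
raster-undersamples them at the model scale, maps both sides to [-1, 1],
and minimizes the stabilized MSE.  Everything is driven by one seed, so the
trained weights are a reproducible function of (data, config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .degrade import bilinear_upsample, raster_undersample
from .image import as_array
from .metrics import MetricsReport, evaluate_pairs
from .optim import AdamW, cosine_lr

__all__ = ["TrainConfig", "stable_mse_loss", "train", "validate", "SRFitResults"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference protocol: AdamW (lr 1e-4, betas (0.9,
    0.999), eps 1e-8, weight decay 1e-4), 130 epochs at batch size 10 with
    cosine annealing over T_max = epochs down to eta_min = 0, and a loss
    stabilizer eps of 1e-8.  ``patch`` is the training crop size (None for
    full-image training, the x8 regime); it must be divisible by the scale.
    """

    lr0: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    weight_decay: float = 1e-4
    epochs: int = 130
    batch_size: int = 10
    t_max: int | None = None  # defaults to epochs
    loss_eps: float = 1e-8
    patch: int | None = 128
    seed: int = 0
    eta_min: float = 0.0
    loss: str = "stable_mse"  # or "stable_rmse"

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss_eps <= 0:
            raise ValueError("loss_eps must be positive")
        if self.t_max is None:
            self.t_max = self.epochs
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.loss not in ("stable_mse", "stable_rmse"):
            raise ValueError("loss must be 'stable_mse' or 'stable_rmse'")


def stable_mse_loss(pred: np.ndarray, target: np.ndarray,
                    eps: float = 1e-8) -> float:
    """Mean squared error plus a small stabilizer eps.

    ``L = mean((y - yhat)^2) + eps``; always >= eps, equal to eps iff the
    prediction matches the target exactly.
    """
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    d = pred - target
    return float(np.mean(d * d) + eps)


def _loss_and_grad(pred, target, cfg: TrainConfig):
    d = pred - target
    n = d.size
    mse = float(np.mean(d * d))
    if cfg.loss == "stable_mse":
        # eps is a constant offset; the gradient is that of plain MSE
        return mse + cfg.loss_eps, (2.0 / n) * d
    root = math.sqrt(mse + cfg.loss_eps)
    return root, d / (n * root)


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    """Stack unit-range (H, W[, C]) images into a signed (N, C, H, W) batch."""
    arrs = []
    for a in images:
        if a.ndim == 2:
            a = a[..., None]
        arrs.append(a.transpose(2, 0, 1))
    return np.stack(arrs) * 2.0 - 1.0


def train(model, hr_images, config: TrainConfig):
    """Fit ``model`` on unit-range high-resolution images.

    Per epoch: one random patch (or the full image when ``patch`` is None)
    per training image, shuffled into batches; per batch: raster
    undersample at the model scale, normalize to [-1, 1], forward, loss,
    backward, AdamW step.  The learning rate follows cosine annealing at
    epoch granularity.

    Returns
    -------
    SRFitResults with the trained model and per-epoch (loss, lr) history.
    """
    if len(hr_images) == 0:
        raise ValueError("empty training set")
    s = model.config.scale
    arrays = [as_array(im) for im in hr_images]
    h0, w0 = arrays[0].shape[:2]
    patch = config.patch
    if patch is not None:
        if patch % s:
            raise ValueError(f"patch {patch} not divisible by scale {s}")
        for a in arrays:
            if a.shape[0] < patch or a.shape[1] < patch:
                raise ValueError("image smaller than the requested patch")
    else:
        for a in arrays:
            if a.shape[:2] != (h0, w0):
                raise ValueError("full-image training requires equal sizes")
            if h0 % s or w0 % s:
                raise ValueError("image size must be divisible by the scale")

    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.lr0, betas=config.betas,
                eps=config.adam_eps, weight_decay=config.weight_decay)
    n = len(arrays)
    history: list[dict] = []

    for epoch in range(config.epochs):
        lr = cosine_lr(epoch, config)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            crops = []
            for i in idx:
                a = arrays[i]
                if patch is None or (a.shape[0] == patch and a.shape[1] == patch):
                    crops.append(a)
                else:
                    top = int(rng.integers(0, a.shape[0] - patch + 1))
                    left = int(rng.integers(0, a.shape[1] - patch + 1))
                    crops.append(a[top:top + patch, left:left + patch])
            hr = _to_batch(crops)
            lr_batch = hr[:, :, ::s, ::s]
            model.zero_grad()
            pred = model.forward(lr_batch, training=True)
            loss, g = _loss_and_grad(pred, hr, config)
            model.backward(g)
            opt.step()
            losses.append(loss)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)), "lr": lr})

    return SRFitResults(model, history, config)


def validate(model, hr_images, scale: int | None = None) -> MetricsReport:
    """Degrade -> super-resolve -> score each image against its ground truth.

    Each unit-range HR image is raster-undersampled at the model scale, run
    through the network, mapped back to [0, 1], and compared with the HR
    original (RMSE / PSNR / SSIM, aggregated mean +- SD).
    """
    if len(hr_images) == 0:
        raise ValueError("empty validation set")
    s = scale if scale is not None else model.config.scale
    if s != model.config.scale:
        raise ValueError("scale does not match the model")
    pairs = []
    for im in hr_images:
        a = as_array(im)
        sr = model.predict(raster_undersample(a, s))
        pairs.append((a, sr))
    return evaluate_pairs(pairs)


def bilinear_baseline(hr_images, scale: int) -> MetricsReport:
    """Score plain bilinear interpolation of the decimated grid (reference)."""
    pairs = []
    for im in hr_images:
        a = as_array(im)
        up = np.clip(bilinear_upsample(raster_undersample(a, scale), scale), 0.0, 1.0)
        pairs.append((a, up))
    return evaluate_pairs(pairs)


class SRFitResults:
    """Result of :func:`train`: trained model, history, diagnostics.

    Attributes
    ----------
    model : LightRepViTSR (training form, weights updated in place)
    history : list of {"epoch", "loss", "lr"} dicts, one per epoch
    config : TrainConfig
    """

    def __init__(self, model, history, config: TrainConfig):
        self.model = model
        self.history = history
        self.config = config

    @property
    def final_loss(self) -> float:
        return self.history[-1]["loss"]

    def validate(self, hr_images, scale: int | None = None) -> MetricsReport:
        return validate(self.model, hr_images, scale)

    def reparameterize(self):
        from .reparam import reparameterize_model

        return reparameterize_model(self.model)

    def summary(self) -> str:
        mc, tc = self.model.config, self.config
        lines = [
            "Light-RepViTSR fit results",
            "==========================",
            f"scale:               x{mc.scale}",
            f"blocks / width:      {mc.n_blocks} / {mc.stem_channels}",
            f"parameters (train):  {self.model.count_parameters()}",
            f"parameters (deploy): {self.model.count_parameters('deploy')}",
            f"epochs / batch:      {tc.epochs} / {tc.batch_size}",
            f"optimizer:           AdamW(lr0={tc.lr0:g}, wd={tc.weight_decay:g})",
            f"schedule:            cosine, T_max={tc.t_max}, eta_min={tc.eta_min:g}",
            f"loss:                {tc.loss} (eps={tc.loss_eps:g})",
            f"first-epoch loss:    {self.history[0]['loss']:.6g}",
            f"final-epoch loss:    {self.history[-1]['loss']:.6g}",
            f"seed:                {tc.seed}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<SRFitResults x{self.model.config.scale}, "
                f"{len(self.history)} epochs, final loss "
                f"{self.final_loss:.3g}>")
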
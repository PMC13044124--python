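"""Image and checkpoint I/O.

Images: 8-bit PNG and 8/16-bit grayscale TIFF round-trips; files are read
into unit-range :class:`~lightsr.image.Image` objects with the source bit
depth recorded.  Checkpoints: an ``.npz`` tensor container next to a JSON
manifest (config, mode, parameter count, seed) sufficient to rebuild the
model exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .image import Image
from .model import LightRepViTSR, ModelConfig

__all__ = ["read_image", "write_image", "save_checkpoint", "load_checkpoint",
           "ImageIOError"]


class ImageIOError(RuntimeError):
    """Raised for unsupported or malformed image files."""


def read_image(path) -> Image:
    """Read a PNG/TIFF into a unit-range Image (bit depth recorded)."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of types
        raise ImageIOError(f"cannot read {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        scale, depth = 255.0, 8
    elif arr.dtype == np.uint16:
        scale, depth = 65535.0, 16
    else:
        raise ImageIOError(f"unsupported dtype {arr.dtype} in {path}")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise ImageIOError(f"unsupported channel count {arr.shape[2]}")
    return Image(arr.astype(np.float64) / scale, "unit",
                 {"path": str(path), "bit_depth": depth})


def write_image(img: Image, path, bit_depth: int | None = None) -> None:
    """Write a unit-range Image as 8-bit PNG or 8/16-bit TIFF."""
    path = Path(path)
    if img.range_tag != "unit":
        from .degrade import normalize

        img = normalize(img, "unit")
    suffix = path.suffix.lower()
    if bit_depth is None:
        bit_depth = 16 if suffix in (".tif", ".tiff") else 8
    data = np.clip(img.data, 0.0, 1.0)
    if bit_depth == 8:
        q = np.round(data * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        q = np.round(data * 65535.0).astype(np.uint16)
    else:
        raise ImageIOError(f"unsupported bit depth {bit_depth}")
    if suffix == ".png":
        if bit_depth == 16:
            raise ImageIOError("16-bit output requires TIFF")
        iio.imwrite(path, q)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    else:
        raise ImageIOError(f"unsupported image format {suffix!r}")


def save_checkpoint(model: LightRepViTSR, path, epoch: int | None = None,
                    extra: dict | None = None) -> None:
    """Write ``<path>.npz`` (tensors) and ``<path>.json`` (manifest)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    manifest = {
        "format": "lightsr-checkpoint-v1",
        "config": model.config.to_dict(),
        "mode": model.mode,
        "init_seed": model.init_seed,
        "parameter_count": model.count_parameters(),
        "epoch": epoch,
    }
    if extra:
        manifest.update(extra)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path) -> LightRepViTSR:
    """Rebuild a model (train or deploy form) from a saved checkpoint."""
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    if manifest.get("format") != "lightsr-checkpoint-v1":
        raise ImageIOError(f"{path}: not a lightsr checkpoint")
    config = ModelConfig(**manifest["config"])
    model = LightRepViTSR(config, init_seed=manifest.get("init_seed", 0))
    if manifest["mode"] == "deploy":
        from .reparam import reparameterize_model

        model = reparameterize_model(model)
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
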
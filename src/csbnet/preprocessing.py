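"""Image normalization, seeded augmentation, and image-folder loading.

Normalization maps raw pixel values affinely onto [-1, 1]:

    x_norm = 2 * (x - x_min) / (x_max - x_min) - 1

with (x_min, x_max) fixed at (0, 255) for 8-bit images rather than computed
per image, so that brightness augmentation keeps its meaning.  A zero-one
variant (x - x_min)/(x_max - x_min) is available for ablation.

Augmentation is applied online, per image: horizontal flip with probability
0.5, vertical flip with probability 0.5, and a brightness factor drawn
uniformly from {1-b, 1, 1+b} (default b = 0.3) applied in raw pixel space
and clipped back to the valid range.  The same seed always reproduces the
same augmented batch bit for bit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}


class ConstantImageError(ValueError):
    pass


@dataclass
class ImageBatch:
    """Normalized images plus labels; the unit of all pipeline flow."""

    pixels: np.ndarray  # (N, 3, 224, 224) float32 in [-1, 1]
    labels: np.ndarray  # (N,) int64 in [0, K)
    class_names: list[str]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.pixels.ndim != 4 or self.pixels.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"pixels {self.pixels.shape} and labels {self.labels.shape} disagree"
            )
        k = len(self.class_names)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError(f"labels must lie in [0, {k})")

    def __len__(self) -> int:
        return self.pixels.shape[0]

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def subset(self, idx: np.ndarray) -> "ImageBatch":
        return ImageBatch(self.pixels[idx], self.labels[idx], list(self.class_names))


def normalize(
    raw: np.ndarray,
    x_min: float = 0.0,
    x_max: float = 255.0,
    zero_one: bool = False,
) -> np.ndarray:
    """Affine rescale of raw pixels onto [-1, 1] (or [0, 1])."""
    if x_max <= x_min:
        raise ConstantImageError(
            f"degenerate pixel range: x_max={x_max} must exceed x_min={x_min}"
        )
    scaled = (np.asarray(raw, dtype=np.float32) - x_min) / (x_max - x_min)
    if zero_one:
        return scaled
    return 2.0 * scaled - 1.0


def denormalize(norm: np.ndarray, x_min: float = 0.0, x_max: float = 255.0) -> np.ndarray:
    """Inverse of :func:`normalize` (the [-1, 1] variant)."""
    return (np.asarray(norm, dtype=np.float32) + 1.0) / 2.0 * (x_max - x_min) + x_min


def augment(
    batch: ImageBatch,
    seed: int,
    p_flip: float = 0.5,
    brightness: float = 0.3,
    enabled: bool = True,
) -> ImageBatch:
    """Seeded per-image flips and brightness jitter on a normalized batch."""
    if not enabled:
        return batch
    rng = np.random.default_rng(seed)
    out = batch.pixels.copy()
    n = len(batch)
    hflip = rng.random(n) < p_flip
    vflip = rng.random(n) < p_flip
    factors = rng.choice(
        np.array([1.0 - brightness, 1.0, 1.0 + brightness], dtype=np.float32), size=n
    )
    out[hflip] = out[hflip][:, :, :, ::-1]
    out[vflip] = out[vflip][:, :, ::-1, :]
    # brightness acts on raw-space intensity: x' = 2*clip(f*(x+1)/2, 0, 1) - 1
    raw01 = (out + 1.0) / 2.0
    raw01 *= factors[:, None, None, None]
    np.clip(raw01, 0.0, 1.0, out=raw01)
    out = 2.0 * raw01 - 1.0
    return ImageBatch(out, batch.labels.copy(), list(batch.class_names))


def load_image_folder(root: str | Path, size: int = 224) -> ImageBatch:
    """Load a class-per-subdirectory image tree into a normalized batch.

    Class order is the sorted subdirectory names; undecodable files are
    skipped with a warning, empty class directories warn.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise ValueError(f"no class subdirectories under {root}")
    pixels, labels = [], []
    class_names = [d.name for d in class_dirs]
    for label, d in enumerate(class_dirs):
        files = sorted(p for p in d.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
        if not files:
            warnings.warn(f"class directory {d} contains no images")
            continue
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB")
                    if im.size != (size, size):
                        im = im.resize((size, size), Image.Resampling.BILINEAR)
                    arr = np.asarray(im, dtype=np.uint8)
            except (UnidentifiedImageError, OSError) as exc:
                logger.warning("skipping undecodable image %s: %s", f, exc)
                continue
            pixels.append(normalize(arr).transpose(2, 0, 1))
            labels.append(label)
    if not pixels:
        raise ValueError(f"no decodable images under {root}")
    return ImageBatch(np.stack(pixels), np.asarray(labels), class_names)
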
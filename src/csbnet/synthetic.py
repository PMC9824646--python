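"""Seeded generator of K-class synthetic leaf images.

Emulates a 4-class maize leaf-disease problem at 224x224x3: every image is
a green elliptical leaf with vein texture on a neutral background, and each
class overlays a distinct lesion archetype —

* ``gray_rect_spots``: small rectangular gray lesions (gray-leaf-spot-like),
* ``tan_streaks``: long tan streaks along the leaf axis (blight-like),
* ``rust_pustules``: dense small orange pustules (rust-like),
* ``healthy``: no lesions.

The archetypes are deliberately separable by coarse colour statistics, so a
classifier that sees even a heavily compressed measurement of the image has
signal to learn from.  This is a statistical stand-in for real leaf
photographs, with no claim to photorealism.  Identical specs produce
bit-identical datasets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .preprocessing import ImageBatch, denormalize, normalize

ARCHETYPES = ("gray_rect_spots", "tan_streaks", "rust_pustules", "healthy")

SIDE = 224


@dataclass
class SyntheticSpec:
    """Generator settings; the seed fully determines the dataset."""

    n_per_class: int = 25
    classes: tuple[str, ...] = ARCHETYPES
    seed: int = 0
    lesion_contrast: float = 1.0  # scales lesion blend strength in (0, 1]
    noise_sigma: float = 4.0  # additive pixel noise, 8-bit units
    leaf_green: tuple[int, int] = (115, 142)  # green-channel range of the blade

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class archetypes must be distinct")
        unknown = set(self.classes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if not (0.0 < self.lesion_contrast <= 1.0):
            raise ValueError("lesion_contrast must lie in (0, 1]")


_YY, _XX = np.mgrid[0:SIDE, 0:SIDE].astype(np.float32)


def _leaf_geometry(rng: np.random.Generator):
    cy = 112 + rng.uniform(-6, 6)
    cx = 112 + rng.uniform(-6, 6)
    a = rng.uniform(82, 92)  # semi-axis along the leaf
    b = rng.uniform(52, 60)
    theta = rng.uniform(-0.45, 0.45)
    ct, st = np.cos(theta), np.sin(theta)
    xr = (_XX - cx) * ct + (_YY - cy) * st  # along-axis coordinate
    yr = -(_XX - cx) * st + (_YY - cy) * ct
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    return mask, xr, yr, a, b


def _blend(img: np.ndarray, region: np.ndarray, color: np.ndarray, alpha: float) -> None:
    img[region] = (1.0 - alpha) * img[region] + alpha * color


def _render(class_name: str, rng: np.random.Generator, spec: SyntheticSpec):
    img = np.empty((SIDE, SIDE, 3), dtype=np.float32)
    img[..., 0] = rng.uniform(113, 119)
    img[..., 1] = rng.uniform(103, 109)
    img[..., 2] = rng.uniform(93, 99)

    mask, xr, yr, a, b = _leaf_geometry(rng)
    g = rng.uniform(*spec.leaf_green)
    leaf_color = np.array([g * rng.uniform(0.42, 0.46), g, g * rng.uniform(0.36, 0.40)],
                          dtype=np.float32)
    shade = 1.0 - 0.25 * ((xr / a) ** 2 + (yr / b) ** 2)
    img[mask] = leaf_color * shade[mask, None]

    # vein texture: central vein plus periodic laterals
    vein = mask & (np.abs(yr) < 1.3)
    spacing = rng.uniform(14, 22)
    lateral = mask & (np.abs((xr + 3 * yr / b) % spacing - spacing / 2) < 0.9)
    img[vein | lateral] *= 0.82

    alpha = 0.9 * spec.lesion_contrast
    lesions = 0
    if class_name == "gray_rect_spots":
        lesions = int(rng.integers(12, 20))
        for _ in range(lesions):
            cx0 = rng.uniform(-a * 0.8, a * 0.8)
            cy0 = rng.uniform(-b * 0.7, b * 0.7)
            w, h = rng.uniform(9, 18), rng.uniform(6, 13)
            region = mask & (np.abs(xr - cx0) < w / 2) & (np.abs(yr - cy0) < h / 2)
            gray = rng.uniform(165, 195)
            _blend(img, region, np.array([gray, gray * 0.98, gray * 0.95]), alpha)
    elif class_name == "tan_streaks":
        lesions = int(rng.integers(5, 10))
        for _ in range(lesions):
            cx0 = rng.uniform(-a * 0.5, a * 0.5)
            cy0 = rng.uniform(-b * 0.75, b * 0.75)
            length, width = rng.uniform(60, 110), rng.uniform(6, 12)
            region = mask & (np.abs(xr - cx0) < length / 2) & (np.abs(yr - cy0) < width / 2)
            color = np.array(
                [rng.uniform(175, 205), rng.uniform(140, 165), rng.uniform(85, 110)],
                dtype=np.float32,
            )
            _blend(img, region, color, alpha)
    elif class_name == "rust_pustules":
        lesions = int(rng.integers(150, 220))
        for _ in range(lesions):
            cx0 = rng.uniform(-a * 0.85, a * 0.85)
            cy0 = rng.uniform(-b * 0.8, b * 0.8)
            r = rng.uniform(2.0, 4.5)
            region = mask & ((xr - cx0) ** 2 + (yr - cy0) ** 2 < r**2)
            color = np.array(
                [rng.uniform(175, 210), rng.uniform(75, 100), rng.uniform(20, 45)],
                dtype=np.float32,
            )
            _blend(img, region, color, alpha)
    elif class_name != "healthy":
        raise ValueError(f"unknown archetype {class_name!r}")

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape).astype(np.float32)
    return np.clip(img, 0, 255).astype(np.uint8), lesions


def _image_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def generate(spec: SyntheticSpec) -> tuple[ImageBatch, dict]:
    """Render the dataset; returns the normalized batch and its manifest."""
    class_names = sorted(spec.classes)
    pixels, labels, entries = [], [], []
    index = 0
    for label, name in enumerate(class_names):
        for i in range(spec.n_per_class):
            img_seed = _image_seed(spec.seed, index)
            rng = np.random.default_rng(img_seed)
            img, lesions = _render(name, rng, spec)
            pixels.append(normalize(img).transpose(2, 0, 1))
            labels.append(label)
            entries.append(
                {
                    "index": index,
                    "file": f"{name}/{name}_{i:04d}.png",
                    "class": name,
                    "label": label,
                    "seed": img_seed,
                    "lesion_count": lesions,
                }
            )
            index += 1
    manifest = {
        "seed": spec.seed,
        "classes": class_names,
        "n_per_class": spec.n_per_class,
        "images": entries,
    }
    batch = ImageBatch(
        np.stack(pixels) if pixels else np.empty((0, 3, SIDE, SIDE), np.float32),
        np.asarray(labels, dtype=np.int64),
        class_names,
    )
    return batch, manifest


def export(batch: ImageBatch, manifest: dict, out_dir: str | Path) -> Path:
    """Write the dataset as a PNG image-folder tree plus manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(batch) == 0:
        warnings.warn(f"exporting an empty batch to {out_dir}")
    for entry in manifest["images"]:
        arr = denormalize(batch.pixels[entry["index"]]).transpose(1, 2, 0)
        img = Image.fromarray(np.clip(np.round(arr), 0, 255).astype(np.uint8))
        path = out_dir / entry["file"]
        path.parent.mkdir(parents=True, exist_ok=True)
        try:
            img.save(path)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
    for name in manifest["classes"]:
        (out_dir / name).mkdir(exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def train_val_split(
    batch: ImageBatch, val_fraction: float = 0.2, seed: int = 0
) -> tuple[ImageBatch, ImageBatch]:
    """Stratified shuffle split into training and validation batches."""
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for label in range(batch.num_classes):
        idx = np.flatnonzero(batch.labels == label)
        rng.shuffle(idx)
        n_val = max(1, int(round(len(idx) * val_fraction))) if len(idx) else 0
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return batch.subset(np.sort(train_idx)), batch.subset(np.sort(val_idx))
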
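"""Dataset loading, augmentation and deterministic stratified splitting.

Datasets follow the image-folder layout used by the SIPAKMED benchmark:
one sub-directory per class (Dyskeratotic, Koilocytotic, Metaplastic,
Parabasal, Superficial-Intermediate), class indices assigned in
alphabetical order of directory name.

Splitting is an 80:10:10 stratified holdout with seed 1337.  The exact
assignment rule is fixed here so it is reproducible across
implementations: per class, indices are shuffled by a generator seeded
with (seed, class index); the first round(test_ratio * n) go to test,
the next round(val_ratio * n) to val, and the remainder to train
(round = half-up).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .config import AugmentationConfig, SplitSpec

__all__ = [
    "LabeledImageSet",
    "load_dataset",
    "stratified_split",
    "augment",
    "eval_transform",
    "load_image",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

logger = logging.getLogger(__name__)

_EXTENSIONS = {".bmp", ".png", ".jpg", ".jpeg"}

# Standard natural-image channel statistics; overridable per call.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class LabeledImageSet:
    """A list of (image path, class index) pairs with the class roster."""

    items: list = field(default_factory=list)  # (path, class_index)
    class_names: list = field(default_factory=list)

    def __len__(self):
        return len(self.items)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c for _, c in self.items], dtype=np.int64)

    @property
    def counts(self) -> dict:
        tally = np.bincount(self.labels, minlength=self.num_classes) if self.items else np.zeros(self.num_classes, dtype=int)
        return {name: int(tally[i]) for i, name in enumerate(self.class_names)}

    def subset(self, indices) -> "LabeledImageSet":
        return LabeledImageSet([self.items[i] for i in indices], list(self.class_names))

    def to_csv(self, path, split_name: str = "", mode: str = "w") -> None:
        with open(path, mode, newline="") as fh:
            writer = csv.writer(fh)
            if mode == "w":
                writer.writerow(["path", "class", "split"])
            for p, c in self.items:
                writer.writerow([p, self.class_names[c], split_name])


def load_image(path) -> Image.Image:
    img = Image.open(path)
    img.load()
    return img.convert("RGB")


def load_dataset(root) -> LabeledImageSet:
    """Scan an image-folder tree into a :class:`LabeledImageSet`.

    Corrupt/undecodable files are skipped with a logged warning; a class
    directory with zero readable images is an error.
    """
    root = Path(root)
    class_dirs = (
        sorted(d for d in root.iterdir() if d.is_dir() and not d.name.startswith(("_", ".")))
        if root.is_dir()
        else []
    )
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class sub-directories")
    class_names = [d.name for d in class_dirs]
    items: list[tuple[str, int]] = []
    skipped = 0
    for idx, d in enumerate(class_dirs):
        readable = 0
        for f in sorted(d.rglob("*")):
            if f.suffix.lower() not in _EXTENSIONS:
                continue
            try:
                with Image.open(f) as img:
                    img.load()
            except Exception:
                logger.warning("skipping unreadable image %s", f)
                skipped += 1
                continue
            items.append((str(f), idx))
            readable += 1
        if readable == 0:
            raise ValueError(f"class {d.name!r} has no readable images")
    if skipped:
        logger.warning("skipped %d unreadable images in total", skipped)
    return LabeledImageSet(items, class_names)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(dataset: LabeledImageSet, spec: SplitSpec | None = None):
    """Deterministic stratified holdout -> (train, val, test) sets."""
    spec = spec or SplitSpec()
    labels = dataset.labels
    train_idx, val_idx, test_idx = [], [], []
    for c in range(dataset.num_classes):
        cls_idx = np.flatnonzero(labels == c)
        n = len(cls_idx)
        if n < 3:
            raise ValueError(
                f"class {dataset.class_names[c]!r} has only {n} items; need >= 3 to split"
            )
        rng = np.random.default_rng([spec.seed, c])
        order = cls_idx[rng.permutation(n)]
        n_test = _round_half_up(spec.test * n)
        n_val = _round_half_up(spec.val * n)
        test_idx.extend(order[:n_test])
        val_idx.extend(order[n_test : n_test + n_val])
        train_idx.extend(order[n_test + n_val :])
    return (
        dataset.subset(sorted(train_idx)),
        dataset.subset(sorted(val_idx)),
        dataset.subset(sorted(test_idx)),
    )


# ---------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------

def _random_resized_crop(img: Image.Image, size: int, scale, rng) -> Image.Image:
    w, h = img.size
    area = w * h
    for _ in range(10):
        target = rng.uniform(scale[0], scale[1]) * area
        aspect = math.exp(rng.uniform(math.log(3 / 4), math.log(4 / 3)))
        cw = int(round(math.sqrt(target * aspect)))
        ch = int(round(math.sqrt(target / aspect)))
        if 0 < cw <= w and 0 < ch <= h:
            left = int(rng.integers(0, w - cw + 1))
            top = int(rng.integers(0, h - ch + 1))
            return img.resize((size, size), Image.BILINEAR, box=(left, top, left + cw, top + ch))
    # degenerate window: fall back to a center crop of the short side
    logger.debug("random crop fell back to center crop")
    side = min(w, h)
    left, top = (w - side) // 2, (h - side) // 2
    return img.resize((size, size), Image.BILINEAR, box=(left, top, left + side, top + side))


def _jitter_hue(img: Image.Image, shift: float) -> Image.Image:
    if shift == 0.0:
        return img
    hsv = np.asarray(img.convert("HSV"), dtype=np.int16)
    hsv[..., 0] = (hsv[..., 0] + int(round(shift * 255))) % 256
    return Image.fromarray(hsv.astype(np.uint8), mode="HSV").convert("RGB")


def _median_border_color(img: Image.Image) -> tuple:
    arr = np.asarray(img)
    border = np.concatenate(
        [arr[0].reshape(-1, 3), arr[-1].reshape(-1, 3), arr[:, 0], arr[:, -1]]
    )
    return tuple(int(v) for v in np.median(border, axis=0))


def augment(img: Image.Image, cfg: AugmentationConfig | None = None, rng: np.random.Generator | None = None) -> Image.Image:
    """Training-time augmentation, applied on the fly.

    Order: random-resized crop to ``crop_size``; horizontal / vertical
    flip; rotation uniform in +-``rotation_deg``; brightness, contrast,
    saturation and hue jitter.  Out-of-frame pixels from the rotation
    are filled with the image's median border color.
    """
    from PIL import ImageEnhance

    cfg = cfg or AugmentationConfig()
    rng = rng or np.random.default_rng()
    if img.mode != "RGB":
        img = img.convert("RGB")
    img = _random_resized_crop(img, cfg.crop_size, cfg.crop_scale, rng)
    if rng.random() < cfg.hflip_p:
        img = img.transpose(Image.FLIP_LEFT_RIGHT)
    if rng.random() < cfg.vflip_p:
        img = img.transpose(Image.FLIP_TOP_BOTTOM)
    if cfg.rotation_deg > 0:
        angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        img = img.rotate(angle, Image.BILINEAR, fillcolor=_median_border_color(img))
    for factor, enhancer in (
        (cfg.brightness, ImageEnhance.Brightness),
        (cfg.contrast, ImageEnhance.Contrast),
        (cfg.saturation, ImageEnhance.Color),
    ):
        if factor > 0:
            img = enhancer(img).enhance(rng.uniform(1 - factor, 1 + factor))
    if cfg.hue > 0:
        img = _jitter_hue(img, rng.uniform(-cfg.hue, cfg.hue))
    return img


def eval_transform(
    img: Image.Image,
    size: int = 224,
    mean: np.ndarray = IMAGENET_MEAN,
    std: np.ndarray = IMAGENET_STD,
) -> np.ndarray:
    """Deterministic eval-time transform -> float32 CHW tensor.

    Resize to ``size`` x ``size``, scale to [0, 1], standardize each
    channel with the given statistics.
    """
    if img.mode != "RGB":
        img = img.convert("RGB")
    img = img.resize((size, size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    arr = (arr - mean) / std
    return arr.transpose(2, 0, 1)


def to_tensor_batch(
    dataset: LabeledImageSet,
    indices=None,
    size: int = 224,
    train: bool = False,
    aug_cfg: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Materialize (images, labels) arrays for a subset of a dataset."""
    if indices is None:
        indices = range(len(dataset))
    xs, ys = [], []
    for i in indices:
        path, label = dataset.items[i]
        img = load_image(path)
        if train:
            img = augment(img, aug_cfg or AugmentationConfig(crop_size=size), rng)
        xs.append(eval_transform(img, size=size))
        ys.append(label)
    return np.stack(xs), np.array(ys, dtype=np.int64)
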
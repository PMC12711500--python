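"""Synthetic Pap-smear-like cell image fixtures.

Renders class-conditional single-cell crops in the SIPAKMED image-folder
layout so the whole pipeline can be built and tested without downloading
anything.  Each image is background noise plus a cytoplasm ellipse, a
nucleus ellipse and chromatin speckles; classes differ in
nucleus-to-cytoplasm (N:C) area ratio, nucleus eccentricity, chromatin
speckle density and stain darkness — echoing the morphological cues a
cytologist uses (elevated N:C ratio and hyperchromasia for dysplastic
cells).  The generator also emits a per-image ground-truth nucleus mask
so attribution heatmaps have a localizable target.

Everything is synthetic: these are geometric cartoons of cells, not
renderings of real cytology.  They give the classes a known, separable
signal; they do not carry staining variability, debris, overlapping
cells or focus artifacts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import LabeledImageSet

__all__ = [
    "ClassMorphology",
    "FixtureProfile",
    "sipakmed_profile",
    "tiny_profile",
    "generate_fixtures",
    "render_cell",
]

# Per-class image counts of the SIPAKMED benchmark.
SIPAKMED_COUNTS = {
    "Dyskeratotic": 813,
    "Koilocytotic": 825,
    "Metaplastic": 793,
    "Parabasal": 787,
    "Superficial-Intermediate": 813,
}


@dataclass
class ClassMorphology:
    """Morphology ranges for one synthetic class."""

    count: int = 32
    nc_ratio: tuple = (0.2, 0.35)  # nucleus / cytoplasm area, in (0, 1)
    eccentricity: tuple = (0.2, 0.6)
    speckle_density: float = 0.1  # fraction of nucleus pixels speckled
    nucleus_shade: float = 1.0  # >1 darkens the nucleus (hyperchromasia)
    halo: bool = False  # perinuclear clearing (koilocytes)

    def validate(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not (0.0 < self.nc_ratio[0] <= self.nc_ratio[1] < 1.0):
            raise ValueError(f"N:C ratio range must lie in (0, 1), got {self.nc_ratio}")


@dataclass
class FixtureProfile:
    """A full synthetic-dataset recipe."""

    classes: dict = field(default_factory=dict)  # name -> ClassMorphology
    image_size_range: tuple = (48, 72)
    noise: float = 0.03  # background Gaussian noise, fraction of full scale
    seed: int = 0

    def validate(self):
        lo, hi = self.image_size_range
        if not (32 <= lo <= hi <= 512):
            raise ValueError(f"image size range must lie within [32, 512], got {self.image_size_range}")
        for morph in self.classes.values():
            morph.validate()


def sipakmed_profile(counts: dict | None = None, seed: int = 0, image_size_range=(48, 72)) -> FixtureProfile:
    """A five-class profile shaped like the SIPAKMED benchmark."""
    counts = counts or SIPAKMED_COUNTS
    morphology = {
        "Dyskeratotic": ClassMorphology(
            nc_ratio=(0.45, 0.65), eccentricity=(0.5, 0.85),
            speckle_density=0.3, nucleus_shade=1.35,
        ),
        "Koilocytotic": ClassMorphology(
            nc_ratio=(0.15, 0.28), eccentricity=(0.3, 0.6),
            speckle_density=0.12, halo=True,
        ),
        "Metaplastic": ClassMorphology(
            nc_ratio=(0.28, 0.42), eccentricity=(0.2, 0.5),
            speckle_density=0.1,
        ),
        "Parabasal": ClassMorphology(
            nc_ratio=(0.2, 0.3), eccentricity=(0.1, 0.3),
            speckle_density=0.08,
        ),
        "Superficial-Intermediate": ClassMorphology(
            nc_ratio=(0.03, 0.08), eccentricity=(0.1, 0.4),
            speckle_density=0.05,
        ),
    }
    classes = {}
    for name, morph in morphology.items():
        if name in counts:
            morph.count = counts[name]
            classes[name] = morph
    return FixtureProfile(classes=classes, image_size_range=image_size_range, seed=seed)


def tiny_profile(per_class: int = 32, num_classes: int = 2, seed: int = 0, image_size: int = 64) -> FixtureProfile:
    """A small N-class profile whose classes differ only in nucleus size.

    With the N:C ratio as the sole discriminative cue, a classifier that
    separates these classes must attend to the nucleus — which is what
    the attribution checks rely on.
    """
    nc_ranges = [(0.05, 0.10), (0.40, 0.50), (0.20, 0.28), (0.60, 0.70), (0.31, 0.37)]
    if num_classes > len(nc_ranges):
        raise ValueError(f"tiny profile supports at most {len(nc_ranges)} classes")
    classes = {
        f"class{i}_nc{int(nc_ranges[i][0] * 100):02d}": ClassMorphology(
            count=per_class, nc_ratio=nc_ranges[i], eccentricity=(0.2, 0.4),
            speckle_density=0.0,
        )
        for i in range(num_classes)
    }
    return FixtureProfile(classes=classes, image_size_range=(image_size, image_size), seed=seed)


# ---------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------

_BACKGROUND = np.array([232, 228, 238], dtype=np.float32)
_CYTOPLASM = np.array([196, 158, 200], dtype=np.float32)
_NUCLEUS = np.array([96, 64, 128], dtype=np.float32)


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float, angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_cell(morph: ClassMorphology, size: int, noise: float, rng: np.random.Generator):
    """Render one synthetic cell -> (uint8 HxWx3 image, bool nucleus mask)."""
    img = np.broadcast_to(_BACKGROUND, (size, size, 3)).copy()
    img += rng.normal(0.0, noise * 255.0, img.shape)

    # cytoplasm ellipse covering ~25-45 % of the frame
    cyto_area = rng.uniform(0.25, 0.45) * size * size
    ecc_c = rng.uniform(0.1, 0.5)
    ratio_c = np.sqrt(1.0 - ecc_c**2)
    a_c = np.sqrt(cyto_area / (np.pi * ratio_c))
    b_c = a_c * ratio_c
    cx = size / 2 + rng.uniform(-0.05, 0.05) * size
    cy = size / 2 + rng.uniform(-0.05, 0.05) * size
    ang_c = rng.uniform(0, np.pi)
    cyto = _ellipse_mask(size, cx, cy, a_c, b_c, ang_c)
    tint = rng.uniform(-12, 12, 3)
    img[cyto] = _CYTOPLASM + tint + rng.normal(0.0, noise * 180.0, (int(cyto.sum()), 3))

    # nucleus ellipse with the class's N:C area ratio and eccentricity
    nc = rng.uniform(*morph.nc_ratio)
    ecc_n = rng.uniform(*morph.eccentricity)
    ratio_n = np.sqrt(1.0 - ecc_n**2)
    nuc_area = nc * cyto.sum()
    a_n = np.sqrt(nuc_area / (np.pi * ratio_n))
    b_n = a_n * ratio_n
    off = 0.25 * max(b_c - a_n, 0.0)
    ncx = cx + rng.uniform(-off, off)
    ncy = cy + rng.uniform(-off, off)
    ang_n = rng.uniform(0, np.pi)
    nucleus = _ellipse_mask(size, ncx, ncy, a_n, b_n, ang_n) & cyto

    if morph.halo:
        halo = _ellipse_mask(size, ncx, ncy, a_n * 1.6, b_n * 1.6, ang_n) & cyto & ~nucleus
        img[halo] = img[halo] * 0.35 + _BACKGROUND * 0.65

    color_n = _NUCLEUS / morph.nucleus_shade
    img[nucleus] = color_n + rng.normal(0.0, noise * 120.0, (int(nucleus.sum()), 3))

    if morph.speckle_density > 0 and nucleus.any():
        speckle = (rng.random((size, size)) < morph.speckle_density) & nucleus
        img[speckle] = color_n * 0.45

    return np.clip(img, 0, 255).astype(np.uint8), nucleus, cyto


def generate_fixtures(profile: FixtureProfile, out_dir) -> LabeledImageSet:
    """Write a synthetic dataset (BMP images + nucleus masks + manifest).

    Fully reproducible: per-image RNG streams are derived from
    (profile.seed, class index, image index), so re-running with the
    same profile yields byte-identical files.
    """
    profile.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    class_names = sorted(profile.classes)
    items = []
    manifest_rows = []
    lo, hi = profile.image_size_range
    for c, name in enumerate(class_names):
        morph = profile.classes[name]
        cls_dir = out_dir / name
        mask_dir = out_dir / "_masks" / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        mask_dir.mkdir(parents=True, exist_ok=True)
        for i in range(morph.count):
            rng = np.random.default_rng([profile.seed, c, i])
            size = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            img, mask, cyto = render_cell(morph, size, profile.noise, rng)
            img_path = cls_dir / f"{name}_{i:04d}.bmp"
            mask_path = mask_dir / f"{name}_{i:04d}.png"
            Image.fromarray(img).save(img_path)
            Image.fromarray(mask.astype(np.uint8) * 255).save(mask_path)
            items.append((str(img_path), c))
            manifest_rows.append(
                [
                    str(img_path.relative_to(out_dir)),
                    name,
                    str(mask_path.relative_to(out_dir)),
                    int(mask.sum()),
                    int(cyto.sum()),
                    size,
                ]
            )
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "mask", "nucleus_area", "cytoplasm_area", "image_size"])
        writer.writerows(manifest_rows)
    return LabeledImageSet(items, class_names)
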
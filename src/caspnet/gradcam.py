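"""Grad-CAM attribution at the final convolutional (SPPF) output.

For a target class c with logit y_c and the hooked feature map
A in R^{K x H x W}:

    alpha_k = mean over (i, j) of  d y_c / d A_k[i, j]
    raw map = ReLU( sum_k alpha_k A_k )

The raw map is min-max normalized to [0, 1] per image (an all-zero map
stays all-zero) and bilinearly upsampled to the input resolution.  The
SPPF merge conv is the default target layer — the last convolutional
output before pooling — with the CSP merge conv available behind a
flag.  The computation reads gradients only; model parameters are never
modified.

A simple localization score accompanies the heatmaps for the synthetic
fixtures: the fraction of total heatmap mass that falls inside the
ground-truth nucleus mask (optionally dilated by a margin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation

from .model import CASPNet

__all__ = ["Heatmap", "grad_cam", "localization_check", "save_heatmap", "save_overlay"]


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    raw: np.ndarray  # pre-normalization, non-negative
    upsampled: np.ndarray  # (input_size, input_size) in [0, 1]
    target_class: int


def cam_weighted_sum(activation: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """The raw Grad-CAM map: ReLU of the alpha-weighted channel sum,
    alpha_k being the spatial mean of the channel's gradient."""
    alpha = np.asarray(grads).mean(axis=(1, 2))
    return np.maximum((alpha[:, None, None] * np.asarray(activation)).sum(axis=0), 0.0)


def _normalize(raw: np.ndarray) -> np.ndarray:
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def _bilinear_upsample(grid: np.ndarray, size: int) -> np.ndarray:
    img = Image.fromarray(grid.astype(np.float32), mode="F")
    return np.asarray(img.resize((size, size), Image.BILINEAR), dtype=np.float32)


def grad_cam(model: CASPNet, image: np.ndarray, target_class: int, layer: str = "sppf") -> Heatmap:
    """Compute a class-discriminative heatmap for one image.

    ``image`` is (C, H, W) or (1, C, H, W); the model is evaluated in
    eval mode (deterministic).
    """
    if not 0 <= target_class < model.cfg.num_classes:
        raise ValueError(
            f"target class {target_class} out of range [0, {model.cfg.num_classes})"
        )
    if layer not in ("sppf", "csp"):
        raise ValueError("layer must be 'sppf' or 'csp'")
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 3:
        image = image[None]
    was_training = model.training
    model.eval()
    model.cam_layer = layer
    try:
        logits = model(image)
        logits.backward(_one_hot_grad(logits.data.shape, target_class))
        activation = model.cam_activation
    finally:
        model.cam_layer = None
        model.cam_activation = None
        model.zero_grad()
        model.train(was_training)
    grads = activation.grad
    if grads is None:
        grads = np.zeros_like(activation.data)
    raw = cam_weighted_sum(activation.data[0], grads[0])
    if raw.max() == 0:
        import logging

        logging.getLogger(__name__).info(
            "grad-cam: zero gradient everywhere; returning an all-zero heatmap"
        )
    values = _normalize(raw)
    upsampled = _bilinear_upsample(values, image.shape[-1])
    return Heatmap(values=values, raw=raw, upsampled=upsampled, target_class=target_class)


def _one_hot_grad(shape, target_class: int) -> np.ndarray:
    g = np.zeros(shape, dtype=np.float32)
    g[:, target_class] = 1.0
    return g


def localization_check(heatmap: Heatmap, mask: np.ndarray, dilate_px: int = 0) -> dict:
    """Fraction of heatmap mass inside the (optionally dilated) mask.

    Returns {"in_mask", "in_dilated_mask", "mask_fraction",
    "dilated_mask_fraction"}; the *_fraction entries are the area
    baselines a spatially uniform heatmap would score.
    """
    hm = heatmap.upsampled
    mask = np.asarray(mask).astype(bool)
    if mask.shape != hm.shape:
        raise ValueError(f"mask shape {mask.shape} != heatmap shape {hm.shape}")
    total = hm.sum()
    dilated = binary_dilation(mask, iterations=dilate_px) if dilate_px > 0 else mask
    if total <= 0:
        return {
            "in_mask": 0.0,
            "in_dilated_mask": 0.0,
            "mask_fraction": float(mask.mean()),
            "dilated_mask_fraction": float(dilated.mean()),
        }
    return {
        "in_mask": float(hm[mask].sum() / total),
        "in_dilated_mask": float(hm[dilated].sum() / total),
        "mask_fraction": float(mask.mean()),
        "dilated_mask_fraction": float(dilated.mean()),
    }


def save_heatmap(heatmap: Heatmap, path) -> None:
    """Grayscale PNG of the upsampled heatmap."""
    Image.fromarray((heatmap.upsampled * 255).astype(np.uint8)).save(path)


def save_overlay(heatmap: Heatmap, image: np.ndarray, path, alpha: float = 0.45, cmap: str = "jet") -> None:
    """Alpha-blend the colorized heatmap over the (C, H, W) input image."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import colormaps

    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 4:
        img = img[0]
    img = img.transpose(1, 2, 0)
    img = (img - img.min()) / max(img.max() - img.min(), 1e-8)
    colored = colormaps[cmap](heatmap.upsampled)[..., :3]
    blend = (1 - alpha) * img + alpha * colored
    Image.fromarray((np.clip(blend, 0, 1) * 255).astype(np.uint8)).save(path)
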
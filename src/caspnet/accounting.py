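"""Parameter and FLOP accounting for the classifier and its ablations.

FLOPs use the multiply-accumulate convention over matrix products only
(convolutions, linear layers, and the Q K^T / attention-times-V products
inside self-attention).  Normalizations, activations, pooling and other
element-wise work are excluded.  Counting is done by instrumenting the
matmul primitive during a single batch-1 forward pass, so the figure is
exact for whatever geometry is requested rather than estimated from a
formula.
"""

from __future__ import annotations

import json

import numpy as np

from . import autodiff as ad
from . import nn
from .config import ArchConfig
from .model import CASPNet, build_variant

__all__ = ["count_parameters", "count_flops", "model_summary", "summary_text"]


def count_parameters(model: nn.Module) -> int:
    """Total element count of all trainable parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def count_flops(model: nn.Module, image_size: int | None = None, in_channels: int = 3) -> int:
    """MACs of one forward pass at batch 1 for the given input geometry."""
    if image_size is None:
        image_size = model.cfg.image_size
        in_channels = model.cfg.in_channels
    was_training = model.training
    model.eval()
    x = np.zeros((1, in_channels, image_size, image_size), dtype=np.float32)
    with ad.no_grad(), ad.count_macs() as box:
        model(x)
    model.train(was_training)
    return int(box["macs"])


def _per_module_counts(model: nn.Module) -> dict:
    counts: dict[str, int] = {}
    for name, _ in model._modules.items():
        sub = model._modules[name]
        counts[name] = int(sum(p.data.size for p in sub.parameters()))
    return counts


def model_summary(model: CASPNet, image_size: int | None = None) -> dict:
    """Per-component parameter counts, total, and FLOPs at a geometry."""
    total = count_parameters(model)
    flops = count_flops(model, image_size)
    return {
        "variant": model.variant,
        "per_module_parameters": _per_module_counts(model),
        "total_parameters": total,
        "total_parameters_millions": round(total / 1e6, 2),
        "flops": flops,
        "flops_g": round(flops / 1e9, 3),
        "image_size": image_size if image_size is not None else model.cfg.image_size,
    }


def summary_text(summary: dict) -> str:
    lines = [f"variant: {summary['variant']}  (input {summary['image_size']}px)"]
    for name, count in summary["per_module_parameters"].items():
        lines.append(f"  {name:<14} {count:>12,d} params")
    lines.append(f"  {'total':<14} {summary['total_parameters']:>12,d} params "
                 f"({summary['total_parameters_millions']:.2f} M)")
    lines.append(f"  {'flops':<14} {summary['flops']:>12,d} MACs "
                 f"({summary['flops_g']:.3f} G)")
    return "\n".join(lines)


def variant_summaries(cfg: ArchConfig, variants=("full", "vit_only", "csp_sppf_only", "vit_csp")) -> list:
    """Accounting rows for a list of variants (no training involved)."""
    rows = []
    for name in variants:
        model = build_variant(name, cfg)
        rows.append(model_summary(model))
    return rows


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
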
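"""Loss, AdamW optimizer, one-cycle schedule and the training loop.

The loss is multi-class cross-entropy: for sample i with true class y_i
and predicted probabilities p_i, loss_i = -log p_{i, y_i}, reduced by
the batch mean and computed through a max-subtracted log-softmax for
stability.

AdamW performs the decoupled-weight-decay update

    m <- b1 m + (1 - b1) g        v <- b2 v + (1 - b2) g^2
    m^ = m / (1 - b1^t)           v^ = v / (1 - b2^t)
    theta <- theta - lr * m^ / (sqrt(v^) + eps) - lr * wd * theta

with the decay applied directly to the parameters, never mixed into the
gradient.  Normalization parameters, biases and the class/positional
embedding tokens are excluded from decay, following standard practice.
The L2 penalty lr-free form (wd * sum w^2) is available separately as a
reporting quantity.

The learning-rate schedule is a one-cycle cosine: warm up from
``initial_lr`` to ``max_lr`` over the first ``warmup_fraction`` of the
optimizer steps, then anneal to ``final_lr``; both phases are cosine
interpolations and the curve is continuous at the peak.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .config import ArchConfig, AugmentationConfig, TrainingConfig
from .data import LabeledImageSet, to_tensor_batch
from .model import CASPNet, build_variant

__all__ = [
    "cross_entropy",
    "weight_decay_penalty",
    "AdamW",
    "one_cycle_lr",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "predict",
]


def cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean negative log-likelihood of the true classes."""
    labels = np.asarray(labels, dtype=np.int64)
    n, C = logits.shape
    if labels.shape != (n,):
        raise ValueError(f"labels shape {labels.shape} does not match batch {n}")
    bad = np.flatnonzero((labels < 0) | (labels >= C))
    if bad.size:
        raise IndexError(f"label out of range [0, {C}) at sample {int(bad[0])}")
    logp = ad.log_softmax(logits, axis=-1)
    picked = logp[np.arange(n), labels]
    return picked.mean() * -1.0


def decayed_parameter_names(model: nn.Module) -> list:
    """Parameters subject to weight decay: weight matrices only —
    biases, norm scales and the embedding tokens are excluded."""
    names = []
    for name, p in model.named_parameters():
        if p.data.ndim < 2:
            continue
        leaf = name.rsplit(".", 1)[-1]
        if leaf in ("cls_token", "pos_embed"):
            continue
        names.append(name)
    return names


def weight_decay_penalty(model_or_params, weight_decay: float) -> float:
    """Reporting-only L2 penalty: wd * sum of squared decayed weights.

    (The optimizer applies decay in decoupled form; this quantity is
    never added to the gradient.)
    """
    if isinstance(model_or_params, nn.Module):
        allowed = set(decayed_parameter_names(model_or_params))
        arrays = [p.data for n, p in model_or_params.named_parameters() if n in allowed]
    else:
        arrays = [np.asarray(p.data if isinstance(p, Tensor) else p) for p in model_or_params]
    return float(weight_decay) * float(sum((a.astype(np.float64) ** 2).sum() for a in arrays))


class AdamW:
    """Decoupled-weight-decay Adam over a model's named parameters."""

    def __init__(self, model: nn.Module, cfg: TrainingConfig | None = None, lr: float | None = None):
        cfg = cfg or TrainingConfig()
        self.cfg = cfg
        self.lr = lr if lr is not None else cfg.max_lr
        self.params = dict(model.named_parameters())
        self.decayed = set(decayed_parameter_names(model))
        self.t = 0
        self.m = {n: np.zeros_like(p.data) for n, p in self.params.items()}
        self.v = {n: np.zeros_like(p.data) for n, p in self.params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        b1, b2, eps, wd = self.cfg.beta1, self.cfg.beta2, self.cfg.epsilon, self.cfg.weight_decay
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for name, p in self.params.items():
            g = p.grad
            if g is None:
                g = np.zeros_like(p.data)
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient in parameter {name!r}")
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / bc1
            v_hat = v / bc2
            update = self.lr * m_hat / (np.sqrt(v_hat) + eps)
            if wd > 0 and name in self.decayed:
                update = update + self.lr * wd * p.data
            p.data = p.data - update

    def state_dict(self) -> dict:
        return {"t": self.t, "m": {k: v.copy() for k, v in self.m.items()},
                "v": {k: v.copy() for k, v in self.v.items()}}

    def load_state_dict(self, state: dict):
        self.t = state["t"]
        self.m = {k: np.asarray(v) for k, v in state["m"].items()}
        self.v = {k: np.asarray(v) for k, v in state["v"].items()}


def one_cycle_lr(step: int, total_steps: int, cfg: TrainingConfig | None = None) -> float:
    """One-cycle cosine learning rate at an optimizer step in [0, total]."""
    cfg = cfg or TrainingConfig()
    if total_steps < 2:
        raise ValueError("total_steps must be >= 2")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    peak = cfg.warmup_fraction * total_steps

    def cosine(a: float, b: float, t: float) -> float:
        return a + (b - a) * 0.5 * (1.0 - np.cos(np.pi * t))

    if step <= peak:
        return float(cosine(cfg.initial_lr, cfg.max_lr, step / peak))
    return float(cosine(cfg.max_lr, cfg.final_lr, (step - peak) / (total_steps - peak)))


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: CASPNet, path, extra: dict | None = None) -> None:
    """Single-file snapshot: parameters + the ArchConfig that built them."""
    payload = {
        "arch": asdict(model.cfg),
        "state": model.state_dict(),
        "extra": extra or {},
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path) -> CASPNet:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    arch = payload["arch"]
    arch["head_hidden"] = list(arch["head_hidden"])
    cfg = ArchConfig(**arch)
    model = CASPNet(cfg)
    model.load_state_dict(payload["state"])
    return model


# ---------------------------------------------------------------------
# loop
# ---------------------------------------------------------------------

def predict(model: CASPNet, images: np.ndarray, batch_size: int = 32):
    """Eval-mode class probabilities and argmax predictions."""
    was_training = model.training
    model.eval()
    probs = []
    with ad.no_grad():
        for lo in range(0, len(images), batch_size):
            logits = model(images[lo : lo + batch_size])
            probs.append(ad.softmax(logits, axis=-1).data)
    model.train(was_training)
    probs = np.concatenate(probs) if probs else np.zeros((0, model.cfg.num_classes))
    return probs, probs.argmax(axis=1)


def _accuracy(model, images, labels) -> float:
    _, preds = predict(model, images)
    return float((preds == labels).mean())


def train(
    model: CASPNet,
    train_set: LabeledImageSet,
    val_set: LabeledImageSet | None,
    cfg: TrainingConfig,
    aug_cfg: AugmentationConfig | None = None,
    max_steps: int | None = None,
    checkpoint_path=None,
    augment_train: bool = True,
    log=None,
):
    """Seeded training loop with per-step one-cycle scheduling.

    Returns (model, history): history is a list of per-epoch dicts
    (epoch, lr, train_loss, train_acc, val_acc).  The best-validation
    checkpoint is kept when ``checkpoint_path`` is given.
    """
    if len(train_set) == 0:
        raise ValueError("training split is empty")
    nn.manual_seed(cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    size = model.cfg.image_size
    n = len(train_set)
    steps_per_epoch = max(1, (n + cfg.batch_size - 1) // cfg.batch_size)
    total_steps = steps_per_epoch * cfg.epochs
    if max_steps is not None:
        total_steps = min(total_steps, max_steps)
    optimizer = AdamW(model, cfg)
    history = []
    best_val = -1.0
    step = 0
    done = False
    for epoch in range(cfg.epochs):
        if done:
            break
        model.train()
        order = rng.permutation(n)
        epoch_loss, epoch_correct, epoch_seen = 0.0, 0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            images, labels = to_tensor_batch(
                train_set, idx, size=size, train=augment_train, aug_cfg=aug_cfg, rng=rng
            )
            optimizer.lr = one_cycle_lr(step, total_steps, cfg)
            optimizer.zero_grad()
            logits = model(images)
            loss = cross_entropy(logits, labels)
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item() * len(idx)
            epoch_correct += int((logits.data.argmax(axis=1) == labels).sum())
            epoch_seen += len(idx)
            step += 1
            if max_steps is not None and step >= max_steps:
                done = True
                break
        record = {
            "epoch": epoch,
            "lr": optimizer.lr,
            "train_loss": epoch_loss / max(epoch_seen, 1),
            "train_acc": epoch_correct / max(epoch_seen, 1),
        }
        if val_set is not None and len(val_set) > 0:
            val_images, val_labels = to_tensor_batch(val_set, size=size)
            record["val_acc"] = _accuracy(model, val_images, val_labels)
            if checkpoint_path is not None and record["val_acc"] >= best_val:
                best_val = record["val_acc"]
                save_checkpoint(model, checkpoint_path, extra={"epoch": epoch, "val_acc": best_val})
        elif checkpoint_path is not None:
            save_checkpoint(model, checkpoint_path, extra={"epoch": epoch})
        history.append(record)
        if log is not None:
            log(record)
    return model, history


def history_to_csv(history: list, path) -> None:
    import csv as _csv

    keys = sorted({k for row in history for k in row})
    with open(path, "w", newline="") as fh:
        writer = _csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)


def history_to_json(history: list, path) -> None:
    with open(path, "w") as fh:
        json.dump(history, fh, indent=2)
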
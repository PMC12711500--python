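"""Loss closed forms, AdamW update equations, one-cycle schedule and the
determinism of the training loop."""

import numpy as np
import pytest

from caspnet import nn
from caspnet.autodiff import Tensor
from caspnet.config import TrainingConfig
from caspnet.model import build_variant
from caspnet.training import (
    AdamW,
    cross_entropy,
    decayed_parameter_names,
    load_checkpoint,
    one_cycle_lr,
    predict,
    train,
    weight_decay_penalty,
)

from oracles import adamw_ref_trajectory, cross_entropy_ref


# --------------------------------------------------------- cross-entropy
def test_cross_entropy_perfect_prediction_tends_to_zero():
    logits = Tensor(np.array([[30.0, 0.0, 0.0]], np.float32))
    assert cross_entropy(logits, [0]).item() == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("C", [2, 5, 7])
def test_cross_entropy_uniform_is_log_C(C):
    logits = Tensor(np.zeros((4, C), np.float32))
    loss = cross_entropy(logits, np.zeros(4, dtype=int))
    assert loss.item() == pytest.approx(np.log(C), rel=1e-6)


def test_cross_entropy_hand_softmax_value():
    """-log(e^2 / (e^2 + e^1 + e^0)) = 0.40761 for logits (2,1,0), label 0."""
    logits = Tensor(np.array([[2.0, 1.0, 0.0]], np.float32))
    got = cross_entropy(logits, [0]).item()
    assert got == pytest.approx(0.40761, abs=1e-4)
    assert got == pytest.approx(cross_entropy_ref([[2.0, 1.0, 0.0]], [0]), abs=1e-6)


def test_cross_entropy_is_stable_for_large_logits():
    logits = Tensor(np.array([[1000.0, 999.0], [-1000.0, -999.0]], np.float32))
    loss = cross_entropy(logits, [0, 1])
    assert np.isfinite(loss.item())
    want = cross_entropy_ref([[1000.0, 999.0], [-1000.0, -999.0]], [0, 1])
    assert loss.item() == pytest.approx(want, rel=1e-5)


def test_cross_entropy_rejects_out_of_range_label():
    with pytest.raises(IndexError, match="sample 1"):
        cross_entropy(Tensor(np.zeros((2, 3), np.float32)), [0, 5])


def test_cross_entropy_gradient_matches_finite_differences():
    """Analytic backward vs central differences of an independent float64
    implementation of the same loss."""
    rng = np.random.default_rng(0)
    logits = rng.standard_normal((4, 5)).astype(np.float32)
    labels = np.array([1, 0, 4, 2])
    t = Tensor(logits, requires_grad=True)
    cross_entropy(t, labels).backward()
    h = 1e-5
    fd = np.zeros_like(logits, dtype=np.float64)
    base = logits.astype(np.float64)
    for i in range(4):
        for j in range(5):
            up, down = base.copy(), base.copy()
            up[i, j] += h
            down[i, j] -= h
            fd[i, j] = (cross_entropy_ref(up, labels) - cross_entropy_ref(down, labels)) / (2 * h)
    np.testing.assert_allclose(t.grad, fd, atol=1e-4)


# ---------------------------------------------------------- weight decay
def test_weight_decay_penalty_closed_forms():
    w = Tensor(np.array([3.0, 4.0], np.float32))
    assert weight_decay_penalty([w], 0.0) == 0.0
    assert weight_decay_penalty([w], 0.1) == pytest.approx(2.5)
    reshaped = Tensor(np.array([[3.0], [4.0]], np.float32))
    assert weight_decay_penalty([reshaped], 0.1) == pytest.approx(2.5)


def test_decay_exclusions_cover_norms_biases_and_embeddings(tiny_cfg):
    nn.manual_seed(0)
    model = build_variant("full", tiny_cfg)
    decayed = set(decayed_parameter_names(model))
    assert not any("bias" in n or "norm" in n for n in decayed)
    assert "encoder.cls_token" not in decayed
    assert "encoder.pos_embed" not in decayed
    assert any(n.endswith("weight") for n in decayed)


# ------------------------------------------------------------------ AdamW
class _Scalar(nn.Module):
    def __init__(self, value):
        super().__init__()
        self.theta = nn.Parameter(np.array([value], np.float32))
        # treat as a decayed matrix for the optimizer tests
        self.theta.data = self.theta.data.reshape(1, 1)


def test_adamw_pure_decay_closed_form():
    """Zero gradient, fresh state: theta' = theta - lr*wd*theta."""
    model = _Scalar(1.0)
    cfg = TrainingConfig(weight_decay=0.05)
    opt = AdamW(model, cfg, lr=0.001)
    model.theta.grad = np.zeros((1, 1), np.float32)
    opt.step()
    assert model.theta.data[0, 0] == pytest.approx(0.99995, abs=1e-9)


def test_adamw_first_step_closed_form():
    """g=0.5, wd=0: m^=0.5, v^=0.25, update ~= -lr."""
    model = _Scalar(0.0)
    cfg = TrainingConfig(weight_decay=0.0)
    opt = AdamW(model, cfg, lr=0.001)
    model.theta.grad = np.full((1, 1), 0.5, np.float32)
    opt.step()
    assert model.theta.data[0, 0] == pytest.approx(-0.001, rel=1e-4)


@pytest.mark.parametrize("wd", [0.0, 0.05])
def test_adamw_ten_steps_match_reference_recurrences(wd):
    """Ten steps on a quadratic toy loss track an independently coded
    float64 reference of the same recurrences (float32 storage floor)."""
    model = _Scalar(1.0)
    cfg = TrainingConfig(weight_decay=wd)
    opt = AdamW(model, cfg, lr=0.01)
    grads = []
    trajectory = []
    for _ in range(10):
        g = 2.0 * model.theta.data  # d/dtheta theta^2
        grads.append(g.copy())
        model.theta.grad = g.astype(np.float32)
        opt.step()
        trajectory.append(model.theta.data.copy())
    ref = adamw_ref_trajectory(
        np.array([[1.0]]), grads, 0.01, cfg.beta1, cfg.beta2, cfg.epsilon, wd, decay=wd > 0
    )
    np.testing.assert_allclose(
        np.array(trajectory).ravel(), np.array(ref).ravel(), atol=1e-6
    )


def test_adamw_rejects_non_finite_gradients():
    model = _Scalar(1.0)
    opt = AdamW(model, TrainingConfig())
    model.theta.grad = np.array([[np.nan]], np.float32)
    with pytest.raises(FloatingPointError, match="theta"):
        opt.step()


# --------------------------------------------------------------- schedule
def test_one_cycle_endpoints_and_peak():
    cfg = TrainingConfig()
    total = 1000
    assert one_cycle_lr(0, total, cfg) == pytest.approx(1e-4)
    assert one_cycle_lr(100, total, cfg) == pytest.approx(1e-3)  # 10 % of training
    assert one_cycle_lr(total, total, cfg) == pytest.approx(1e-5)


def test_one_cycle_is_unimodal_and_continuous():
    cfg = TrainingConfig()
    total = 500
    lrs = np.array([one_cycle_lr(s, total, cfg) for s in range(total + 1)])
    peak = lrs.argmax()
    assert np.all(np.diff(lrs[: peak + 1]) >= -1e-12)  # rises
    assert np.all(np.diff(lrs[peak:]) <= 1e-12)  # then falls
    # per-step change bounded by the analytic cosine slope of each phase
    warm = int(cfg.warmup_fraction * total)
    bound_up = (cfg.max_lr - cfg.initial_lr) * np.pi / (2 * warm)
    bound_down = (cfg.max_lr - cfg.final_lr) * np.pi / (2 * (total - warm))
    assert np.abs(np.diff(lrs[:warm])).max() <= bound_up * 1.001
    assert np.abs(np.diff(lrs[warm:])).max() <= bound_down * 1.001


def test_one_cycle_rejects_out_of_range_step():
    with pytest.raises(ValueError):
        one_cycle_lr(11, 10)
    with pytest.raises(ValueError):
        one_cycle_lr(0, 1)


# ------------------------------------------------------------------- loop
def test_train_requires_nonempty_split(tiny_cfg):
    from caspnet.data import LabeledImageSet

    model = build_variant("full", tiny_cfg)
    with pytest.raises(ValueError, match="empty"):
        train(model, LabeledImageSet([], ["a", "b"]), None, TrainingConfig())


def test_history_and_lr_trace(tiny_dataset, tiny_cfg):
    _, dataset = tiny_dataset
    nn.manual_seed(1)
    model = build_variant("full", tiny_cfg)
    cfg = TrainingConfig(batch_size=32, epochs=3, seed=99)
    model, history = train(model, dataset, None, cfg, augment_train=False)
    assert len(history) == 3
    steps_per_epoch = int(np.ceil(len(dataset) / 32))
    total = steps_per_epoch * 3
    for epoch, rec in enumerate(history):
        first_step_of_epoch = epoch * steps_per_epoch
        assert rec["lr"] == pytest.approx(one_cycle_lr(first_step_of_epoch + steps_per_epoch - 1, total, cfg))


def test_two_seeded_runs_have_identical_histories(tiny_dataset, tiny_cfg):
    _, dataset = tiny_dataset
    cfg = TrainingConfig(batch_size=16, epochs=2, seed=55)

    def run():
        nn.manual_seed(7)
        model = build_variant("full", tiny_cfg)
        _, history = train(model, dataset, None, cfg, augment_train=False)
        return history

    a, b = run(), run()
    assert a == b


def test_checkpoint_resume_preserves_shapes_and_config(tmp_path, tiny_dataset, tiny_cfg):
    _, dataset = tiny_dataset
    nn.manual_seed(3)
    model = build_variant("full", tiny_cfg)
    cfg = TrainingConfig(batch_size=32, epochs=1, seed=5)
    path = tmp_path / "best.ckpt"
    train(model, dataset, dataset, cfg, checkpoint_path=path, augment_train=False)
    resumed = load_checkpoint(path)
    assert resumed.cfg == model.cfg
    for p, q in zip(resumed.parameters(), model.parameters()):
        assert p.data.shape == q.data.shape


def test_overfit_smoke_two_class_fixture(overfit_bundle):
    """A depth-reduced model separates the two synthetic classes after a
    short training run."""
    model = overfit_bundle["model"]
    _, preds = predict(model, overfit_bundle["images"])
    acc = float((preds == overfit_bundle["labels"]).mean())
    assert acc >= 0.95
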
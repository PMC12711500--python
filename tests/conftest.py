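"""Shared fixtures: a tiny architecture for fast end-to-end work, a small
synthetic two-class dataset, a model overfit on it, and the full-size
default model (built once per session — it holds ~91 M parameters)."""

import csv

import numpy as np
import pytest
from PIL import Image

from caspnet import nn
from caspnet.config import ArchConfig, TrainingConfig
from caspnet.data import to_tensor_batch
from caspnet.fixtures import generate_fixtures, tiny_profile
from caspnet.model import build_variant
from caspnet.training import train


def tiny_arch(**overrides) -> ArchConfig:
    """A depth-reduced configuration that keeps every pipeline stage."""
    defaults = dict(
        image_size=64,
        patch_size=16,
        embed_dim=64,
        depth=2,
        num_heads=4,
        num_classes=2,
        csp_mid=32,
        sppf_mid=32,
        head_hidden=[32],
        dropout=0.0,
        attn_dropout=0.0,
    )
    defaults.update(overrides)
    return ArchConfig(**defaults)


@pytest.fixture
def tiny_cfg() -> ArchConfig:
    return tiny_arch()


@pytest.fixture(scope="session")
def default_full_model():
    """The full-size default model (224 px, ViT-Base backbone)."""
    nn.manual_seed(1337)
    return build_variant("full").eval()


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Two classes x 32 synthetic cells differing only in nucleus size."""
    root = tmp_path_factory.mktemp("tinydata")
    dataset = generate_fixtures(tiny_profile(per_class=32, num_classes=2, seed=7), root)
    return root, dataset


@pytest.fixture(scope="session")
def tiny_masks(tiny_dataset):
    root, dataset = tiny_dataset
    manifest = {
        str(root / row["path"]): root / row["mask"]
        for row in csv.DictReader(open(root / "manifest.csv"))
    }
    masks = {}
    for path, _ in dataset.items:
        masks[path] = np.asarray(Image.open(manifest[path]).resize((64, 64), Image.NEAREST)) > 127
    return masks


@pytest.fixture(scope="session")
def overfit_bundle(tiny_dataset):
    """Tiny model trained 200 steps on the two-class fixture set."""
    _, dataset = tiny_dataset
    cfg = tiny_arch()
    nn.manual_seed(0)
    model = build_variant("full", cfg)
    tcfg = TrainingConfig(batch_size=16, epochs=50, seed=123)
    model, history = train(model, dataset, None, tcfg, max_steps=200, augment_train=False)
    images, labels = to_tensor_batch(dataset, size=64)
    return {
        "model": model.eval(),
        "dataset": dataset,
        "history": history,
        "images": images,
        "labels": labels,
    }
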
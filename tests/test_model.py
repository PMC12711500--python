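"""Architecture behaviour: patch embedding, attention, the token-to-
spatial bridge, CSP/SPPF blocks, head, variants, and determinism."""

import numpy as np
import pytest

import caspnet.autodiff as ad
from caspnet import nn
from caspnet.accounting import count_parameters
from caspnet.autodiff import Tensor
from caspnet.config import ArchConfig, ConfigError
from caspnet.model import (
    CASPNet,
    ClassificationHead,
    CSPBlock,
    SPPFBlock,
    ViTEncoder,
    build_variant,
    global_average_pool,
    spatial_to_tokens,
    tokens_to_spatial,
)
from caspnet.training import load_checkpoint, save_checkpoint

from oracles import attention_loop, patch_embed_loop, sliding_window_max


# ---------------------------------------------------------------- patches
def test_patch_embedding_token_counts():
    nn.manual_seed(0)
    pe = nn.PatchConv(3, 8, 16)
    assert pe(Tensor(np.zeros((1, 3, 224, 224), np.float32))).shape == (1, 196, 8)
    assert pe(Tensor(np.zeros((1, 3, 32, 32), np.float32))).shape == (1, 4, 8)


def test_patch_embedding_rejects_nondivisible_geometry():
    pe = nn.PatchConv(3, 8, 16)
    with pytest.raises(ValueError, match="48x40"):
        pe(Tensor(np.zeros((1, 3, 48, 40), np.float32)))


def test_patch_embedding_matches_patch_loop_oracle():
    nn.manual_seed(1)
    pe = nn.PatchConv(3, 6, 16)
    x = np.random.default_rng(0).standard_normal((2, 3, 32, 32)).astype(np.float32)
    got = pe(Tensor(x)).data
    want = patch_embed_loop(x, pe.weight.data, pe.bias.data, 16)
    np.testing.assert_allclose(got, want, atol=1e-5)


# -------------------------------------------------------------- attention
def _set_attention_weights(attn, rng):
    for p in attn.parameters():
        p.data = rng.standard_normal(p.data.shape).astype(np.float32) * 0.5


def test_attention_rows_sum_to_one():
    nn.manual_seed(2)
    attn = nn.MultiHeadAttention(8, 2)
    attn.eval()
    x = Tensor(np.random.default_rng(1).standard_normal((2, 5, 8)).astype(np.float32))
    attn(x)
    rows = attn._last_attn.sum(axis=-1)
    np.testing.assert_allclose(rows, 1.0, atol=1e-6)
    assert (attn._last_attn >= 0).all()


def test_single_token_attention_is_projected_value():
    nn.manual_seed(3)
    attn = nn.MultiHeadAttention(8, 2)
    attn.eval()
    _set_attention_weights(attn, np.random.default_rng(2))
    x = np.random.default_rng(3).standard_normal((1, 1, 8)).astype(np.float32)
    got = attn(Tensor(x)).data
    qkv = x[0] @ attn.qkv.weight.data.T + attn.qkv.bias.data
    v = qkv[:, 16:24]
    want = v @ attn.proj.weight.data.T + attn.proj.bias.data
    np.testing.assert_allclose(got[0], want, atol=1e-5)


def test_attention_matches_loop_oracle():
    """Two-token toy vs explicit-loop softmax(QK^T/sqrt(d))V."""
    nn.manual_seed(4)
    attn = nn.MultiHeadAttention(4, 2)
    attn.eval()
    _set_attention_weights(attn, np.random.default_rng(4))
    x = np.random.default_rng(5).standard_normal((2, 4)).astype(np.float32)
    got = attn(Tensor(x[None])).data[0]
    w = attn.qkv.weight.data
    b = attn.qkv.bias.data
    want = attention_loop(
        x, w[:4], b[:4], w[4:8], b[4:8], w[8:12], b[8:12],
        attn.proj.weight.data, attn.proj.bias.data, num_heads=2,
    )
    np.testing.assert_allclose(got, want, atol=1e-6)


def test_attention_scale_matches_head_dim():
    attn = nn.MultiHeadAttention(768, 12)
    assert attn.head_dim == 64
    assert attn.scale == pytest.approx(0.125)


# ---------------------------------------------------------------- encoder
def test_encoder_adds_cls_token_and_preserves_shape(tiny_cfg):
    nn.manual_seed(5)
    enc = ViTEncoder(tiny_cfg).eval()
    tokens = Tensor(np.random.default_rng(0).standard_normal((2, 16, 64)).astype(np.float32))
    with_cls = enc.add_cls_and_pos(tokens)
    assert with_cls.shape == (2, 17, 64)
    assert enc(tokens).shape == (2, 17, 64)


def test_add_cls_identity_when_embeddings_zero(tiny_cfg):
    nn.manual_seed(6)
    enc = ViTEncoder(tiny_cfg).eval()
    enc.cls_token.data[:] = 0
    enc.pos_embed.data[:] = 0
    tokens = np.random.default_rng(1).standard_normal((1, 16, 64)).astype(np.float32)
    out = enc.add_cls_and_pos(Tensor(tokens)).data
    np.testing.assert_array_equal(out[:, 1:], tokens)
    np.testing.assert_array_equal(out[:, 0], 0)


def test_add_cls_rejects_token_count_mismatch(tiny_cfg):
    enc = ViTEncoder(tiny_cfg)
    with pytest.raises(ValueError, match="positional embedding"):
        enc.add_cls_and_pos(Tensor(np.zeros((1, 9, 64), np.float32)))


def test_encoder_depth_two_equals_manual_composition(tiny_cfg):
    nn.manual_seed(7)
    enc = ViTEncoder(tiny_cfg).eval()
    x = Tensor(np.random.default_rng(2).standard_normal((1, 17, 64)).astype(np.float32))
    manual = enc.norm(enc.blocks.layers[1](enc.blocks.layers[0](x)))
    np.testing.assert_allclose(enc.run_blocks(x).data, manual.data, atol=1e-6)


# ----------------------------------------------------- token <-> spatial
def test_tokens_to_spatial_shape_and_mapping():
    B, N, D = 1, 197, 3
    tokens = np.zeros((B, N, D), np.float32)
    # patch token k (0-based among the 196) carries value k in channel 0
    tokens[0, 1:, 0] = np.arange(196)
    grid = tokens_to_spatial(Tensor(tokens)).data
    assert grid.shape == (1, 3, 14, 14)
    for k in (0, 13, 14, 195, 27):
        assert grid[0, 0, k // 14, k % 14] == k


def test_tokens_to_spatial_roundtrip_is_exact_identity():
    rng = np.random.default_rng(3)
    spatial = rng.standard_normal((2, 5, 4, 4)).astype(np.float32)
    tokens = spatial_to_tokens(Tensor(spatial)).data
    with_cls = np.concatenate([np.zeros((2, 1, 5), np.float32), tokens], axis=1)
    back = tokens_to_spatial(Tensor(with_cls)).data
    np.testing.assert_array_equal(back, spatial)


def test_tokens_to_spatial_rejects_non_square_grid():
    with pytest.raises(ValueError, match="perfect square"):
        tokens_to_spatial(Tensor(np.zeros((1, 8, 4), np.float32)))


# -------------------------------------------------------------- CSP/SPPF
def test_csp_block_shape_and_parameter_count():
    nn.manual_seed(8)
    csp = CSPBlock(ArchConfig()).eval()
    assert count_parameters(csp) == 2_955_648
    out = csp(Tensor(np.random.default_rng(4).standard_normal((2, 768, 14, 14)).astype(np.float32)))
    assert out.shape == (2, 768, 14, 14)


def test_csp_block_zero_preserving(tiny_cfg):
    nn.manual_seed(9)
    csp = CSPBlock(tiny_cfg).eval()
    out = csp(Tensor(np.zeros((1, 64, 4, 4), np.float32)))
    np.testing.assert_allclose(out.data, 0.0, atol=1e-7)


def test_sppf_concat_width_and_constant_map(tiny_cfg):
    nn.manual_seed(10)
    sppf = SPPFBlock(ArchConfig())
    assert sppf.cv2.conv.in_channels == 1536  # 4 x 384 before the merge conv
    tiny = SPPFBlock(tiny_cfg).eval()
    const = np.full((1, 64, 4, 4), 3.25, np.float32)
    y0 = tiny.cv1(Tensor(const))
    y1 = tiny.pool(y0)
    np.testing.assert_array_equal(y1.data, y0.data)  # max of a constant map


def test_sppf_cascade_equals_single_wide_pools():
    """Two cascaded 5x5 pools == one 9x9; three == one 13x13 (stride 1,
    same padding), against a brute-force sliding-window-max oracle."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal((1, 4, 14, 14)).astype(np.float32)
    t = Tensor(x)
    p1 = ad.max_pool2d(t, 5, 1, 2)
    p2 = ad.max_pool2d(p1, 5, 1, 2)
    p3 = ad.max_pool2d(p2, 5, 1, 2)
    np.testing.assert_allclose(p2.data, sliding_window_max(x, 9), atol=1e-5)
    np.testing.assert_allclose(p3.data, sliding_window_max(x, 13), atol=1e-5)


# ------------------------------------------------------------- GAP / head
def test_global_average_pool_matches_manual_mean():
    x = np.random.default_rng(6).standard_normal((1, 3, 2, 2)).astype(np.float32)
    got = global_average_pool(Tensor(x)).data
    want = (x[:, :, 0, 0] + x[:, :, 0, 1] + x[:, :, 1, 0] + x[:, :, 1, 1]) / 4.0
    np.testing.assert_allclose(got, want, rtol=1e-6)
    const = np.full((2, 5, 3, 3), -1.5, np.float32)
    np.testing.assert_array_equal(global_average_pool(Tensor(const)).data, -1.5)


def test_head_logit_width_and_parameter_count():
    nn.manual_seed(11)
    head = ClassificationHead(ArchConfig()).eval()
    assert count_parameters(head) == 527_877
    out = head(Tensor(np.random.default_rng(7).standard_normal((3, 768)).astype(np.float32)))
    assert out.shape == (3, 5)


def test_head_all_zero_weights_give_uniform_softmax(tiny_cfg):
    nn.manual_seed(12)
    head = ClassificationHead(ArchConfig(num_classes=5)).eval()
    for p in head.parameters():
        p.data[:] = 0
    head.norm.weight.data[:] = 1  # keep LN affine at identity
    logits = head(Tensor(np.random.default_rng(8).standard_normal((2, 768)).astype(np.float32)))
    np.testing.assert_array_equal(logits.data, 0)
    probs = ad.softmax(logits, axis=-1).data
    np.testing.assert_allclose(probs, 0.2, atol=1e-7)


def test_head_rejects_wrong_feature_dim(tiny_cfg):
    head = ClassificationHead(tiny_cfg)
    with pytest.raises(ValueError, match="feature dim"):
        head(Tensor(np.zeros((1, 48), np.float32)))


# ---------------------------------------------------------------- variants
def test_unknown_variant_lists_valid_names():
    with pytest.raises(ValueError, match="vit_only"):
        build_variant("resnet")


def test_variant_parameter_relationships(tiny_cfg):
    nn.manual_seed(13)
    full = build_variant("full", tiny_cfg)
    vit_csp = build_variant("vit_csp", tiny_cfg)
    sppf_params = count_parameters(full.sppf)
    assert count_parameters(full) - count_parameters(vit_csp) == sppf_params


def test_csp_sppf_only_has_no_encoder(tiny_cfg):
    model = build_variant("csp_sppf_only", tiny_cfg)
    names = {name for name, _ in model.named_modules()}
    assert not any(n.startswith("encoder") for n in names)
    assert any(n.startswith("csp.transformer") for n in names)  # branch-2 block remains


@pytest.mark.parametrize("variant", ["full", "vit_only", "csp_sppf_only", "vit_csp"])
def test_every_variant_produces_finite_logits(variant, tiny_cfg):
    nn.manual_seed(14)
    model = build_variant(variant, tiny_cfg).eval()
    x = np.random.default_rng(9).standard_normal((2, 3, 64, 64)).astype(np.float32)
    with ad.no_grad():
        out = model(x)
    assert out.shape == (2, 2)
    assert np.isfinite(out.data).all()


# ------------------------------------------------------------- properties
def test_eval_mode_forward_is_bitwise_deterministic(tiny_cfg):
    nn.manual_seed(15)
    model = build_variant("full", tiny_cfg).eval()
    x = np.random.default_rng(10).standard_normal((2, 3, 64, 64)).astype(np.float32)
    with ad.no_grad():
        a = model(x).data
        b = model(x).data
    np.testing.assert_array_equal(a, b)


def test_batch_permutation_permutes_logits(tiny_cfg):
    nn.manual_seed(16)
    model = build_variant("full", tiny_cfg).eval()
    x = np.random.default_rng(11).standard_normal((4, 3, 64, 64)).astype(np.float32)
    perm = np.array([2, 0, 3, 1])
    with ad.no_grad():
        straight = model(x).data
        permuted = model(x[perm]).data
    np.testing.assert_allclose(permuted, straight[perm], atol=1e-5)


def test_config_invariants_enforced():
    with pytest.raises(ConfigError):
        ArchConfig(image_size=100, patch_size=16)
    with pytest.raises(ConfigError):
        ArchConfig(embed_dim=100, num_heads=12)
    with pytest.raises(ConfigError):
        ArchConfig(dropout=1.5)
    with pytest.raises(ConfigError):
        ArchConfig(variant="unknown")


def test_checkpoint_roundtrip_bitwise(tmp_path, tiny_cfg):
    nn.manual_seed(17)
    model = build_variant("full", tiny_cfg)
    path = tmp_path / "model.ckpt"
    save_checkpoint(model, path)
    clone = load_checkpoint(path)
    assert clone.cfg == model.cfg
    for (name, p), (name2, q) in zip(model.named_parameters(), clone.named_parameters()):
        assert name == name2
        np.testing.assert_array_equal(p.data, q.data)
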
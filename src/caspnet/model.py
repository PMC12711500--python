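"""The hybrid ViT + CSP/SPPF cervical-cell classifier and its ablations.

The full pipeline is

    patch embedding -> [CLS + positional embedding] -> 12 transformer
    blocks -> final LayerNorm -> drop CLS + reshape tokens onto the
    14x14 patch grid -> CSP block -> SPPF block -> global average pool
    -> MLP classification head -> logits

The bridge between the token and spatial worlds is a parameter-free,
exactly invertible reshape: patch token k (0-based, after removing the
class token) lands on grid cell (k // 14, k % 14), channels first.

Ablation variants share one :class:`~caspnet.config.ArchConfig`:

``full``
    the whole pipeline above.
``vit_only``
    encoder only; the class token feeds the classification head.
``vit_csp``
    full pipeline minus the SPPF block.
``csp_sppf_only``
    the patch conv acts as a 16x16-stride stem straight into the
    spatial grid (no class token, no encoder), then CSP -> SPPF ->
    pool -> head.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .config import VARIANTS, ArchConfig

__all__ = [
    "PatchEmbed",
    "ViTEncoder",
    "CSPBlock",
    "SPPFBlock",
    "ClassificationHead",
    "CASPNet",
    "build_variant",
    "tokens_to_spatial",
    "spatial_to_tokens",
    "global_average_pool",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def tokens_to_spatial(tokens) -> Tensor:
    """Drop the class token and reshape patch tokens onto their 2-D grid.

    (B, N, D) -> (B, D, H, W) with H = W = sqrt(N - 1), row-major: patch
    token k maps to cell (k // W, k % W).  Zero trainable parameters and
    exactly invertible (see :func:`spatial_to_tokens`).
    """
    tokens = _as_tensor(tokens)
    B, N, D = tokens.shape
    side = int(round(np.sqrt(N - 1)))
    if side * side != N - 1:
        raise ValueError(f"token count {N} minus CLS is not a perfect square")
    patches = tokens[:, 1:, :]
    return patches.reshape(B, side, side, D).transpose(0, 3, 1, 2)


def spatial_to_tokens(x) -> Tensor:
    """Inverse of :func:`tokens_to_spatial` minus the class token:
    (B, C, H, W) -> (B, H*W, C), row-major."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    return x.transpose(0, 2, 3, 1).reshape(B, H * W, C)


def global_average_pool(x) -> Tensor:
    """Arithmetic mean of each channel over both spatial axes: (B,C,H,W) -> (B,C)."""
    return _as_tensor(x).mean(axis=(2, 3))


class PatchEmbed(nn.Module):
    """Cut the image into non-overlapping patches, project each to a token.

    The projection is a strided conv (kernel = stride = patch size)
    followed by a parameter-free layer normalization over the embedding
    axis, so the published parameter budget is preserved.
    """

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        self.cfg = cfg
        self.proj = nn.PatchConv(cfg.in_channels, cfg.embed_dim, cfg.patch_size)
        self.norm = nn.LayerNorm(cfg.embed_dim, affine=False)

    def forward(self, image) -> Tensor:
        return self.norm(self.proj(_as_tensor(image)))


class ViTEncoder(nn.Module):
    """Class/positional embeddings plus a stack of transformer blocks."""

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        self.cfg = cfg
        self.cls_token = nn.Parameter(nn.trunc_normal((1, 1, cfg.embed_dim)))
        self.pos_embed = nn.Parameter(
            nn.trunc_normal((1, cfg.num_patches + 1, cfg.embed_dim))
        )
        self.pos_drop = nn.Dropout(cfg.dropout)
        self.blocks = nn.Sequential(
            *[
                nn.TransformerBlock(
                    cfg.embed_dim,
                    cfg.num_heads,
                    cfg.mlp_ratio,
                    cfg.qkv_bias,
                    cfg.dropout,
                    cfg.attn_dropout,
                )
                for _ in range(cfg.depth)
            ]
        )
        self.norm = nn.LayerNorm(cfg.embed_dim)

    def add_cls_and_pos(self, tokens) -> Tensor:
        """Prepend the learnable class token, add positional embeddings,
        apply embedding dropout (training mode only)."""
        tokens = _as_tensor(tokens)
        B, N, D = tokens.shape
        if N + 1 != self.pos_embed.shape[1]:
            raise ValueError(
                f"got {N} patch tokens but positional embedding expects "
                f"{self.pos_embed.shape[1] - 1}"
            )
        cls = self.cls_token + Tensor(np.zeros((B, 1, D), dtype=np.float32))
        x = ad.concat([cls, tokens], axis=1)
        return self.pos_drop(x + self.pos_embed)

    def run_blocks(self, x: Tensor) -> Tensor:
        for i, block in enumerate(self.blocks.layers):
            try:
                x = block(x)
            except FloatingPointError as exc:
                raise FloatingPointError(f"block {i}: {exc}") from exc
        return self.norm(x)

    def forward(self, tokens) -> Tensor:
        return self.run_blocks(self.add_cls_and_pos(tokens))


class ConvUnit(nn.Module):
    """1x1 convolution followed by SiLU (no normalization)."""

    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.conv = nn.Conv1x1(in_channels, out_channels)
        self.act = nn.SiLU()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.conv(x))


class CSPBlock(nn.Module):
    """Cross-stage-partial fusion on the spatial map.

    Two parallel 1x1 reductions to ``mid`` channels: branch 1 is the
    shortcut; branch 2 is flattened to tokens and refined by a single
    transformer block (head_dim kept at 64), then reshaped back.  The
    branches are concatenated and merged by a 1x1 conv restoring the
    input width.
    """

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        channels = cfg.embed_dim
        mid = cfg.csp_mid
        heads = max(1, mid // cfg.head_dim)
        self.branch1 = ConvUnit(channels, mid)
        self.branch2 = ConvUnit(channels, mid)
        self.transformer = nn.TransformerBlock(
            mid, heads, cfg.mlp_ratio, cfg.qkv_bias, cfg.dropout, cfg.attn_dropout
        )
        self.merge = ConvUnit(2 * mid, channels)

    def forward(self, x) -> Tensor:
        x = _as_tensor(x)
        _, _, H, W = x.shape
        y1 = self.branch1(x)
        y2 = self.branch2(x)
        t = spatial_to_tokens(y2)
        t = self.transformer(t)
        B, N, C = t.shape
        y2 = t.reshape(B, H, W, C).transpose(0, 3, 1, 2)
        return self.merge(ad.concat([y1, y2], axis=1))


class SPPFBlock(nn.Module):
    """Spatial-pyramid-pooling-fast: three cascaded 5x5 stride-1 max
    pools whose outputs are concatenated with the reduced input and
    merged by a 1x1 conv.  Cascading 5x5 pools yields effective 9x9 and
    13x13 receptive fields at the cost of one kernel."""

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        channels = cfg.embed_dim
        mid = cfg.sppf_mid
        k = cfg.sppf_kernel
        self.cv1 = ConvUnit(channels, mid)
        self.pool = nn.MaxPool2d(k, stride=1, padding=k // 2)
        self.cv2 = ConvUnit(4 * mid, channels)

    def forward(self, x) -> Tensor:
        y0 = self.cv1(_as_tensor(x))
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(ad.concat([y0, y1, y2, y3], axis=1))


class ClassificationHead(nn.Module):
    """LayerNorm then a funnel MLP (768 -> 512 -> 256 -> classes by
    default) with GELU and dropout; returns raw logits."""

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        self.norm = nn.LayerNorm(cfg.embed_dim)
        layers = []
        width = cfg.embed_dim
        for hidden in cfg.head_hidden:
            layers += [nn.Linear(width, hidden), nn.GELU(), nn.Dropout(cfg.dropout)]
            width = hidden
        layers.append(nn.Linear(width, cfg.num_classes))
        self.mlp = nn.Sequential(*layers)

    def forward(self, features) -> Tensor:
        features = _as_tensor(features)
        if features.shape[-1] != self.norm.dim:
            raise ValueError(
                f"feature dim {features.shape[-1]} != head dim {self.norm.dim}"
            )
        return self.mlp(self.norm(features))


class CASPNet(nn.Module):
    """The hybrid classifier; ``cfg.variant`` selects the ablation."""

    def __init__(self, cfg: ArchConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.variant = cfg.variant
        self.patch_embed = PatchEmbed(cfg)
        if self.variant in ("full", "vit_only", "vit_csp"):
            self.encoder = ViTEncoder(cfg)
        if self.variant in ("full", "vit_csp", "csp_sppf_only"):
            self.csp = CSPBlock(cfg)
        if self.variant in ("full", "csp_sppf_only"):
            self.sppf = SPPFBlock(cfg)
        self.head = ClassificationHead(cfg)
        # Grad-CAM support: when enabled, the forward pass keeps a handle
        # on the requested convolutional output ("sppf" or "csp").
        self.cam_layer: str | None = None
        self.cam_activation: Tensor | None = None

    # -- stages exposed individually ----------------------------------
    def embed_patches(self, image) -> Tensor:
        return self._stage("patch embedding", self.patch_embed, _as_tensor(image))

    def _stage(self, name: str, fn, *args) -> Tensor:
        try:
            return fn(*args)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    def _maybe_retain(self, name: str, x: Tensor) -> Tensor:
        if self.cam_layer == name:
            x.retain_grad()
            self.cam_activation = x
        return x

    def forward(self, image) -> Tensor:
        image = _as_tensor(image)
        if image.ndim != 4:
            raise ValueError(f"expected a (B, C, H, W) image batch, got {image.shape}")
        self.cam_activation = None
        x = self.embed_patches(image)
        if self.variant == "vit_only":
            x = self._stage("encoder", self.encoder, x)
            return self._stage("head", self.head, x[:, 0, :])
        if self.variant == "csp_sppf_only":
            B, N, D = x.shape
            side = int(round(np.sqrt(N)))
            x = x.reshape(B, side, side, D).transpose(0, 3, 1, 2)
        else:
            x = self._stage("encoder", self.encoder, x)
            x = self._stage("token-to-spatial reshape", tokens_to_spatial, x)
        x = self._maybe_retain("csp", self._stage("csp", self.csp, x))
        if self.variant in ("full", "csp_sppf_only"):
            x = self._maybe_retain("sppf", self._stage("sppf", self.sppf, x))
        x = self._stage("global average pool", global_average_pool, x)
        return self._stage("head", self.head, x)


def build_variant(name: str, cfg: ArchConfig | None = None) -> CASPNet:
    """Build one of the ablation variants sharing a single ArchConfig."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; valid variants: {VARIANTS}")
    import dataclasses

    cfg = dataclasses.replace(cfg, variant=name) if cfg is not None else ArchConfig(variant=name)
    return CASPNet(cfg)
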
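"""Neural-network layers on top of the autodiff engine.

Provides the module/parameter registry, the layers the hybrid classifier
is assembled from (linear, 1x1 conv, strided patch conv, layer norm,
max-pool, dropout, multi-head self-attention, pre-norm transformer
block) and state-dict (de)serialization.

Initialization is truncated-normal (sigma = 0.02, clipped at two sigma)
for weight matrices and embeddings, zeros for biases, matching common
vision-transformer practice.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "manual_seed",
    "Parameter",
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "GELU",
    "SiLU",
    "Sequential",
    "Conv1x1",
    "PatchConv",
    "MaxPool2d",
    "MultiHeadAttention",
    "Mlp",
    "TransformerBlock",
]

# One generator feeds both parameter init and dropout masks; seeding it
# makes whole runs reproducible.
_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the global generator used for init and dropout."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


def trunc_normal(shape, std: float = 0.02) -> np.ndarray:
    sample = _RNG.standard_normal(shape)
    return (np.clip(sample, -2.0, 2.0) * std).astype(np.float32)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter/submodule registry and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -----------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, m in self._modules.items():
            yield from m.named_modules(prefix + name + ".")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        if missing or unexpected:
            raise KeyError(f"state dict mismatch: missing={missing}, unexpected={unexpected}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(trunc_normal((out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.weight.transpose(1, 0))
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Layer normalization over the last axis, with optional learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.dim = dim
        self.eps = eps
        if affine:
            self.weight = Parameter(np.ones(dim, dtype=np.float32))
            self.bias = Parameter(np.zeros(dim, dtype=np.float32))
        else:
            self.weight = None
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.layer_norm(x, eps=self.eps)
        if self.weight is not None:
            out = out * self.weight + self.bias
        return out


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        return ad.dropout(x, self.p, self.training, _RNG)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.gelu(x)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.silu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv1x1(Module):
    """Pointwise convolution on (B, C, H, W), lowered to a matmul."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.weight = Parameter(trunc_normal((out_channels, in_channels)))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        t = x.transpose(0, 2, 3, 1).reshape(B, H * W, C)
        t = ad.matmul(t, self.weight.transpose(1, 0))
        if self.bias is not None:
            t = t + self.bias
        return t.reshape(B, H, W, self.out_channels).transpose(0, 3, 1, 2)


class PatchConv(Module):
    """Non-overlapping strided convolution (kernel = stride = patch size).

    Equivalent to slicing the image into patches, flattening each in
    (C, ph, pw) order and applying one shared linear projection.
    """

    def __init__(self, in_channels: int, embed_dim: int, patch_size: int):
        super().__init__()
        self.in_channels = in_channels
        self.embed_dim = embed_dim
        self.patch_size = patch_size
        fan_in = in_channels * patch_size * patch_size
        self.weight = Parameter(trunc_normal((embed_dim, fan_in)))
        self.bias = Parameter(np.zeros(embed_dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        p = self.patch_size
        if H % p != 0 or W % p != 0:
            raise ValueError(
                f"image size ({H}x{W}) must be divisible by patch size {p}"
            )
        gh, gw = H // p, W // p
        t = x.reshape(B, C, gh, p, gw, p)
        t = t.transpose(0, 2, 4, 1, 3, 5)  # (B, gh, gw, C, p, p)
        t = t.reshape(B, gh * gw, C * p * p)
        return ad.matmul(t, self.weight.transpose(1, 0)) + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return ad.max_pool2d(x, self.kernel, self.stride, self.padding)


class MultiHeadAttention(Module):
    """Standard multi-head self-attention with fused QKV projection.

    Attention weights are softmax(Q K^T / sqrt(head_dim)); for the
    768-dim, 12-head configuration head_dim = 64 and the scale is 0.125.
    """

    def __init__(
        self,
        dim: int,
        num_heads: int,
        qkv_bias: bool = True,
        attn_drop: float = 0.0,
        proj_drop: float = 0.0,
    ):
        super().__init__()
        if dim % num_heads != 0:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        self.dim = dim
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(dim, 3 * dim, bias=qkv_bias)
        self.proj = Linear(dim, dim)
        self.attn_drop = Dropout(attn_drop)
        self.proj_drop = Dropout(proj_drop)
        self._last_attn: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        B, N, D = x.shape
        qkv = self.qkv(x).reshape(B, N, 3, self.num_heads, self.head_dim)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, heads, N, head_dim)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = ad.softmax(ad.matmul(q, k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        self._last_attn = attn.data
        attn = self.attn_drop(attn)
        out = ad.matmul(attn, v)  # (B, heads, N, head_dim)
        out = out.transpose(0, 2, 1, 3).reshape(B, N, D)
        return self.proj_drop(self.proj(out))


class Mlp(Module):
    """Token-wise feed-forward: expand by mlp_ratio, GELU, project back."""

    def __init__(self, dim: int, hidden: int, drop: float = 0.0):
        super().__init__()
        self.fc1 = Linear(dim, hidden)
        self.fc2 = Linear(hidden, dim)
        self.act = GELU()
        self.drop = Dropout(drop)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.fc2(self.drop(self.act(self.fc1(x)))))


class TransformerBlock(Module):
    """Pre-norm residual block: x += MHSA(LN(x)); x += MLP(LN(x))."""

    def __init__(
        self,
        dim: int,
        num_heads: int,
        mlp_ratio: float = 4.0,
        qkv_bias: bool = True,
        drop: float = 0.0,
        attn_drop: float = 0.0,
    ):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, num_heads, qkv_bias, attn_drop, drop)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), drop)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.mlp(self.norm2(x))
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError("non-finite activations in transformer block")
        return x
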
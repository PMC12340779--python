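"""Neural-network modules: linear layers, layer norm, multi-head attention,
pre-norm transformer blocks, and the vision/text transformer encoders.

The encoders follow the dual-encoder vision-language architecture: a ViT with
a learnable class token whose pooled output is projected to a shared embedding
dimension, and a causal text transformer pooled at the end-of-text token.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .functional import (dropout, gelu, layer_norm,  # noqa: F401 (re-export)
                         log_softmax, softmax)
from .tensor import Tensor, concat, no_grad


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container with named-parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def named_children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    # -- mode --------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _init_normal(rng: np.random.Generator | None, shape, std: float, dtype) -> np.ndarray:
    if rng is None:
        return np.zeros(shape, dtype=dtype)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_init_normal(rng, (out_features, in_features),
                                             in_features ** -0.5, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            y = y + self.bias
        return y


class LoRALinear(Module):
    """A frozen linear layer with a trainable low-rank update.

    Effective weight is ``W0 + (alpha/r) * B @ A`` where ``B`` (out x r) is
    zero-initialized — so the layer is exactly the base layer until the first
    update — and ``A`` (r x in) is small-random.  Dropout is applied to the
    adapter input path only.
    """

    def __init__(self, base: Linear, rank: int, alpha: float, p_dropout: float,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if rank < 1:
            raise ValueError("LoRA rank must be >= 1")
        self.base = base
        self.rank = rank
        self.scale = alpha / rank
        self.p_dropout = p_dropout
        self.lora_A = Parameter((rng.standard_normal((rank, base.in_features))
                                 * base.in_features ** -0.5).astype(dtype))
        self.lora_B = Parameter(np.zeros((base.out_features, rank), dtype=dtype))
        self.rng: np.random.Generator | None = None  # set by the training loop

    def forward(self, x: Tensor) -> Tensor:
        y = self.base(x)
        h = x
        if self.training and self.rng is not None:
            h = dropout(h, self.p_dropout, self.rng, training=True)
        delta = (h @ self.lora_A.transpose(1, 0)) @ self.lora_B.transpose(1, 0)
        return y + delta * self.scale


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=dtype))
        self.bias = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.weight, self.bias, self.eps)


class MultiHeadAttention(Module):
    """Standard scaled dot-product attention with separate Q/K/V projections
    (separate layers make low-rank adapter injection per projection natural)."""

    def __init__(self, width: int, heads: int, rng=None, dtype=np.float32):
        super().__init__()
        if width % heads:
            raise ValueError("width must be divisible by head count")
        self.width = width
        self.heads = heads
        self.head_dim = width // heads
        self.q_proj = Linear(width, width, rng=rng, dtype=dtype)
        self.k_proj = Linear(width, width, rng=rng, dtype=dtype)
        self.v_proj = Linear(width, width, rng=rng, dtype=dtype)
        self.out_proj = Linear(width, width, rng=rng, dtype=dtype)

    def forward(self, x: Tensor, attn_mask: np.ndarray | None = None) -> Tensor:
        n, t, d = x.shape

        def split(z: Tensor) -> Tensor:
            return z.reshape(n, t, self.heads, self.head_dim).transpose(0, 2, 1, 3)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)
        if attn_mask is not None:
            scores = scores + Tensor(attn_mask)
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.out_proj(out)


class TransformerBlock(Module):
    """Pre-norm residual block: x + attn(ln(x)); x + mlp(ln(x)) with a 4x GELU MLP."""

    def __init__(self, width: int, heads: int, rng=None, dtype=np.float32):
        super().__init__()
        self.ln_1 = LayerNorm(width, dtype=dtype)
        self.attn = MultiHeadAttention(width, heads, rng=rng, dtype=dtype)
        self.ln_2 = LayerNorm(width, dtype=dtype)
        self.mlp_fc = Linear(width, width * 4, rng=rng, dtype=dtype)
        self.mlp_proj = Linear(width * 4, width, rng=rng, dtype=dtype)

    def forward(self, x: Tensor, attn_mask: np.ndarray | None = None) -> Tensor:
        x = x + self.attn(self.ln_1(x), attn_mask)
        return x + self.mlp_proj(gelu(self.mlp_fc(self.ln_2(x))))


class VisionTransformer(Module):
    """ViT image encoder: non-overlapping patch embedding, class token,
    learned positional embeddings, pre-norm blocks, and a final linear
    projection of the class token to the shared embedding dimension."""

    def __init__(self, image_size: int, patch_size: int, width: int, depth: int,
                 heads: int, embed_dim: int, rng=None, dtype=np.float32):
        super().__init__()
        if image_size % patch_size:
            raise ValueError("image size must be divisible by patch size")
        self.image_size = image_size
        self.patch_size = patch_size
        self.width = width
        self.grid = image_size // patch_size
        n_patches = self.grid * self.grid
        # patch embedding as a bias-free linear map on flattened patches
        self.patch_embed = Linear(3 * patch_size * patch_size, width, bias=False,
                                  rng=rng, dtype=dtype)
        self.class_embedding = Parameter(_init_normal(rng, (width,), width ** -0.5, dtype))
        self.positional_embedding = Parameter(
            _init_normal(rng, (n_patches + 1, width), width ** -0.5, dtype))
        self.ln_pre = LayerNorm(width, dtype=dtype)
        self.blocks = [TransformerBlock(width, heads, rng=rng, dtype=dtype)
                       for _ in range(depth)]
        self.ln_post = LayerNorm(width, dtype=dtype)
        self.proj = Parameter(_init_normal(rng, (width, embed_dim), width ** -0.5, dtype))

    def _patchify(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        p, g = self.patch_size, self.grid
        x = x.reshape(n, 3, g, p, g, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)  # (n, g, g, 3, p, p)
        return x.reshape(n, g * g, 3 * p * p)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 3, H, W) standardized images -> (N, embed_dim) pooled features."""
        n = x.shape[0]
        tokens = self.patch_embed(self._patchify(x))
        cls = self.class_embedding.reshape(1, 1, self.width).broadcast_to(
            (n, 1, self.width))
        h = concat([cls, tokens], axis=1) + self.positional_embedding
        h = self.ln_pre(h)
        for blk in self.blocks:
            h = blk(h)
        pooled = self.ln_post(h[:, 0, :])
        return pooled @ self.proj


class TextTransformer(Module):
    """Causal text encoder pooled at the end-of-text token, then projected to
    the shared embedding dimension."""

    def __init__(self, vocab_size: int, context_length: int, width: int, depth: int,
                 heads: int, embed_dim: int, rng=None, dtype=np.float32):
        super().__init__()
        self.context_length = context_length
        self.width = width
        self.token_embedding = Parameter(_init_normal(rng, (vocab_size, width), 0.02, dtype))
        self.positional_embedding = Parameter(
            _init_normal(rng, (context_length, width), 0.01, dtype))
        self.blocks = [TransformerBlock(width, heads, rng=rng, dtype=dtype)
                       for _ in range(depth)]
        self.ln_final = LayerNorm(width, dtype=dtype)
        self.text_projection = Parameter(
            _init_normal(rng, (width, embed_dim), width ** -0.5, dtype))

    def forward(self, tokens: np.ndarray, eot_idx: np.ndarray) -> Tensor:
        """tokens: (N, T) int ids; eot_idx: (N,) position of the end-of-text token."""
        tokens = np.asarray(tokens)
        t = tokens.shape[1]
        if t > self.context_length:
            raise ValueError("token sequence exceeds context length")
        h = self.token_embedding.embedding(tokens) + self.positional_embedding[:t]
        mask = np.triu(np.full((t, t), -1e9, dtype=h.dtype), k=1)
        for blk in self.blocks:
            h = blk(h, mask)
        h = self.ln_final(h)
        pooled = h.gather_rows(eot_idx)
        return pooled @ self.text_projection


def freeze(module: Module) -> None:
    for p in module.parameters():
        p.requires_grad = False


def unfreeze(module: Module) -> None:
    for p in module.parameters():
        p.requires_grad = True
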
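"""Dual-encoder architecture with low-rank adapters, attention-MIL view
aggregation, projection and prediction heads, and the loss functions.

The image path encodes each of the nine planar views with a ViT, pools the
per-view features with attention-based multiple-instance learning, and
projects the bag embedding to a 256-dimensional space; the text path encodes
the report and projects to the same space.  The two spaces are aligned with a
symmetric InfoNCE objective on cosine similarities divided by a learnable
temperature (initialized at 0.03 and clamped to [1e-3, 1]), while two linear
prediction heads — one per branch — are trained with class-weighted
cross-entropy on the one-year cancer label.  At inference only the image
branch is needed.

Low-rank adaptation inserts rank-r updates into every query/key/value
projection of both transformers; base weights stay frozen, so only adapters,
the projection heads, the MIL head, the prediction heads, and the temperature
train (0.34% of all parameters at ViT-B/32 dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "EncoderConfig", "LoRAConfig", "MILHead", "NoduleCLIP", "LossBundle",
    "build_model", "inject_lora", "count_trainable", "ParameterCount",
    "mil_aggregate", "info_nce", "clip_loss", "weighted_ce", "l2_normalize",
    "TAU_MIN", "TAU_MAX",
]

TAU_MIN, TAU_MAX = 1e-3, 1.0
EMBED_HEAD_DIM = 256  # shared image/text embedding dimension


@dataclass
class EncoderConfig:
    """Vision + text transformer dimensions.

    ``preset("vitb32")`` replicates the ViT-B/32 dual-encoder dimensions
    (vision: patch 32, width 768, depth 12, input 224; text: width 512,
    depth 12, vocab 49408, context 77; shared embedding 512).
    ``preset("tiny")`` is a desk-scale configuration for tests and the phantom
    study.
    """

    image_size: int = 224
    patch_size: int = 32
    vision_width: int = 768
    vision_depth: int = 12
    vision_heads: int = 12
    text_width: int = 512
    text_depth: int = 12
    text_heads: int = 8
    vocab_size: int = 49408
    context_length: int = 77
    embed_dim: int = 512
    mil_hidden: int = 128
    head_dim: int = EMBED_HEAD_DIM

    def __post_init__(self):
        if self.vision_width % self.vision_heads or self.text_width % self.text_heads:
            raise ValueError("widths must be divisible by head counts")

    @classmethod
    def preset(cls, name: str) -> "EncoderConfig":
        if name == "vitb32":
            return cls()
        if name == "tiny":
            return cls(image_size=56, patch_size=14, vision_width=32,
                       vision_depth=2, vision_heads=2, text_width=32,
                       text_depth=2, text_heads=2, vocab_size=512,
                       context_length=64, embed_dim=32, mil_hidden=16)
        raise KeyError(name)


@dataclass
class LoRAConfig:
    rank: int = 2
    alpha: float = 1.0
    dropout: float = 0.25
    # adapters target every query/key/value projection in both transformers

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


class MILHead(nn.Module):
    """Attention-based multiple-instance pooling (non-gated tanh form):
    a_k = softmax_k(w^T tanh(V h_k)),  z = sum_k a_k h_k."""

    def __init__(self, in_dim: int, hidden: int = 128, rng=None, dtype=np.float32):
        super().__init__()
        self.V = nn.Parameter((np.zeros((hidden, in_dim), dtype=dtype) if rng is None
                               else (rng.standard_normal((hidden, in_dim))
                                     * in_dim ** -0.5).astype(dtype)))
        self.w = nn.Parameter((np.zeros(hidden, dtype=dtype) if rng is None
                               else (rng.standard_normal(hidden)
                                     * hidden ** -0.5).astype(dtype)))

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """h: (B, K, d) bag of K instance features -> (z: (B, d), a: (B, K))."""
        scores = (h @ self.V.transpose(1, 0)).tanh() @ self.w.reshape(-1, 1)
        a = nn.softmax(scores, axis=1)                      # (B, K, 1)
        z = (a.broadcast_to(h.shape[:2] + (1,)) * h).sum(axis=1)
        return z, a.reshape(a.shape[:2])


def mil_aggregate(h, head: MILHead) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate one bag of instance features; returns (z, attention)."""
    arr = np.asarray(h.data if isinstance(h, Tensor) else h)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite instance features")
    z, a = head(Tensor(arr[None]))
    return z.data[0], a.data[0]


class NoduleCLIP(nn.Module):
    """The assembled dual-encoder model."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None,
                 tau_init: float = 0.03, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        self.vision = nn.VisionTransformer(cfg.image_size, cfg.patch_size,
                                           cfg.vision_width, cfg.vision_depth,
                                           cfg.vision_heads, cfg.embed_dim,
                                           rng=rng, dtype=dtype)
        self.text = nn.TextTransformer(cfg.vocab_size, cfg.context_length,
                                       cfg.text_width, cfg.text_depth,
                                       cfg.text_heads, cfg.embed_dim,
                                       rng=rng, dtype=dtype)
        self.mil = MILHead(cfg.embed_dim, cfg.mil_hidden, rng=rng, dtype=dtype)
        self.img_proj = nn.Linear(cfg.embed_dim, cfg.head_dim, bias=False,
                                  rng=rng, dtype=dtype)
        self.txt_proj = nn.Linear(cfg.embed_dim, cfg.head_dim, bias=False,
                                  rng=rng, dtype=dtype)
        self.img_head = nn.Linear(cfg.head_dim, 2, rng=rng, dtype=dtype)
        self.txt_head = nn.Linear(cfg.head_dim, 2, rng=rng, dtype=dtype)
        self.tau = nn.Parameter(np.asarray(tau_init, dtype=dtype))

    # ------------------------------------------------------------- branches
    def encode_views(self, views: np.ndarray) -> tuple[Tensor, Tensor]:
        """views: (B, 9, 3, S, S) -> (bag embedding (B, embed), attention (B, 9))."""
        views = np.asarray(views, dtype=self.tau.data.dtype)
        if views.ndim != 5 or views.shape[1] != 9 or views.shape[2] != 3:
            raise ValueError("expected a (B, 9, 3, S, S) view-stack batch")
        b = views.shape[0]
        flat = Tensor(views.reshape(b * 9, *views.shape[2:]))
        feats = self.vision(flat).reshape(b, 9, self.cfg.embed_dim)
        return self.mil(feats)

    def encode_text(self, tokens: np.ndarray, eot_idx: np.ndarray) -> Tensor:
        return self.text(tokens, eot_idx)

    def forward_pair(self, views: np.ndarray, tokens: np.ndarray,
                     eot_idx: np.ndarray):
        """Full paired forward pass.

        Returns (img_emb, txt_emb, img_logits, txt_logits, attention); the
        embeddings are the unnormalized 256-d projections consumed by the
        prediction heads — normalize before cosine similarity.
        """
        z, a = self.encode_views(views)
        img_emb = self.img_proj(z)
        txt_emb = self.txt_proj(self.encode_text(tokens, eot_idx))
        return img_emb, txt_emb, self.img_head(img_emb), self.txt_head(txt_emb), a

    def forward(self, views, tokens, eot_idx):
        return self.forward_pair(views, tokens, eot_idx)

    def image_logits(self, views: np.ndarray) -> np.ndarray:
        """Inference path: image branch only."""
        with nn.no_grad():
            z, _ = self.encode_views(views)
            return self.img_head(self.img_proj(z)).data

    def clamp_tau(self) -> None:
        self.tau.data = np.clip(self.tau.data, TAU_MIN, TAU_MAX)


def build_model(preset: str | EncoderConfig = "tiny", seed: int = 0,
                tau_init: float = 0.03, init: str = "random",
                dtype=np.float32) -> NoduleCLIP:
    """Assemble a model from a preset name or an explicit config.
    ``init="zeros"`` skips random initialization (useful when weights will be
    loaded or only counted)."""
    cfg = preset if isinstance(preset, EncoderConfig) else EncoderConfig.preset(preset)
    rng = None if init == "zeros" else np.random.default_rng(seed)
    return NoduleCLIP(cfg, rng, tau_init=tau_init, dtype=dtype)


# -------------------------------------------------------------------- LoRA
def inject_lora(model: NoduleCLIP, cfg: LoRAConfig | None = None,
                seed: int = 0) -> NoduleCLIP:
    """Insert rank-r adapters into every Q/K/V projection of both encoders.

    Base weights (the whole of both encoders) are frozen; adapters, the two
    projection heads, the MIL head, the prediction heads and the temperature
    remain trainable.  With B zero-initialized the forward pass is bit
    identical to the unadapted model until the first update.
    """
    cfg = cfg or LoRAConfig()
    rng = np.random.default_rng(seed)
    n_injected = 0
    for encoder in (model.vision, model.text):
        nn.freeze(encoder)
        for mod in encoder.modules():
            if isinstance(mod, nn.MultiHeadAttention):
                for name in ("q_proj", "k_proj", "v_proj"):
                    base = getattr(mod, name)
                    if not isinstance(base, nn.Linear):
                        raise TypeError(f"target layer {name} is not a linear "
                                        "projection; cannot inject adapter")
                    setattr(mod, name, nn.LoRALinear(
                        base, cfg.rank, cfg.alpha, cfg.dropout, rng,
                        dtype=base.weight.data.dtype))
                    n_injected += 1
    if n_injected == 0:
        raise RuntimeError("no query/key/value projections found")
    # re-freeze the wrapped base layers, keep adapters trainable
    for encoder in (model.vision, model.text):
        for mod in encoder.modules():
            if isinstance(mod, nn.LoRALinear):
                nn.freeze(mod.base)
                mod.lora_A.requires_grad = True
                mod.lora_B.requires_grad = True
    return model


class ParameterCount(NamedTuple):
    n_trainable: int
    n_total: int
    percent: float
    n_adapters: int       # trainable parameters inside adapter matrices only
    percent_adapters: float


def count_trainable(model: nn.Module) -> ParameterCount:
    """Exact parameter enumeration; reports both the full trainable budget and
    the adapter-only breakdown."""
    n_train = n_total = n_adapt = 0
    for name, p in model.named_parameters():
        n = int(p.data.size)
        n_total += n
        if p.requires_grad:
            n_train += n
            if "lora_" in name:
                n_adapt += n
    pct = 100.0 * n_train / n_total if n_total else 0.0
    pct_a = 100.0 * n_adapt / n_total if n_total else 0.0
    return ParameterCount(n_train, n_total, pct, n_adapt, pct_a)


# ------------------------------------------------------------------- losses
def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps) ** 0.5
    return x / norm


def info_nce(simmat: Tensor | np.ndarray, tau, direction: str = "image") -> Tensor:
    """InfoNCE over a B x B cosine-similarity matrix with temperature ``tau``.

    ``direction="image"`` classifies each image row against all texts;
    ``direction="semantic"`` classifies each text column against all images
    (the denominator runs over images).  Diagonal entries are the positives.
    """
    simmat = simmat if isinstance(simmat, Tensor) else Tensor(simmat)
    tau_t = tau if isinstance(tau, Tensor) else Tensor(np.asarray(tau, dtype=simmat.dtype))
    if float(tau_t.data) <= 0:
        raise ValueError("temperature must be positive")
    b = simmat.shape[0]
    if simmat.shape != (b, b):
        raise ValueError("similarity matrix must be square")
    logits = simmat / tau_t
    axis = 1 if direction == "image" else 0
    logp = nn.log_softmax(logits, axis=axis)
    eye = Tensor(np.eye(b, dtype=simmat.dtype))
    return -(logp * eye).sum() / b


def clip_loss(simmat: Tensor | np.ndarray, tau) -> Tensor:
    """Average of the image- and semantic-direction InfoNCE losses."""
    return (info_nce(simmat, tau, "image") + info_nce(simmat, tau, "semantic")) * 0.5


def weighted_ce(logits: Tensor | np.ndarray, labels: np.ndarray,
                class_weights: np.ndarray | None = None) -> Tensor:
    """Class-weighted cross-entropy, normalized by the batch's summed weights."""
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n_classes = logits.shape[-1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("label outside the class range")
    if class_weights is None:
        class_weights = np.ones(n_classes)
    class_weights = np.asarray(class_weights, dtype=float)
    if np.any(class_weights <= 0):
        raise ValueError("class weights must be positive")
    w = class_weights[labels].astype(logits.dtype)
    logp = nn.log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    onehot[np.arange(len(labels)), labels] = 1.0
    nll = -(logp * Tensor(onehot)).sum(axis=-1)
    return (nll * Tensor(w)).sum() / float(w.sum())


# -------------------------------------------------------------- checkpoints
def save_checkpoint(model: NoduleCLIP, path, extra: dict | None = None) -> None:
    """Single-file checkpoint: weights plus a JSON-encoded config header.
    With adapters injected, the frozen base can be omitted by filtering the
    state dict before saving."""
    import json

    meta = {"preset_cfg": {k: getattr(model.cfg, k) for k in vars(model.cfg)},
            "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> NoduleCLIP:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = EncoderConfig(**meta["preset_cfg"])
    model = NoduleCLIP(cfg, rng=None)
    lora_names = {k for k in state if ".lora_" in k}
    if lora_names:
        inject_lora(model)
    model.load_state_dict(state)
    return model


@dataclass
class LossBundle:
    """All loss components of one batch; ``total = clip + ce_img + ce_txt``
    with equal weighting."""

    l_img: float
    l_sem: float
    l_clip: float
    ce_img: float
    ce_txt: float
    total_tensor: Tensor = field(repr=False, default=None)

    @property
    def total(self) -> float:
        return self.l_clip + self.ce_img + self.ce_txt


def compute_losses(model: NoduleCLIP, views, tokens, eot_idx, labels,
                   class_weights=None) -> LossBundle:
    """Forward pass plus the full training objective (graph retained in
    ``total_tensor`` for backprop)."""
    img_emb, txt_emb, img_logits, txt_logits, _ = model.forward_pair(
        views, tokens, eot_idx)
    sim = l2_normalize(img_emb) @ l2_normalize(txt_emb).transpose(1, 0)
    l_img = info_nce(sim, model.tau, "image")
    l_sem = info_nce(sim, model.tau, "semantic")
    l_clip = (l_img + l_sem) * 0.5
    ce_i = weighted_ce(img_logits, labels, class_weights)
    ce_t = weighted_ce(txt_logits, labels, class_weights)
    total = l_clip + ce_i + ce_t
    for part, name in ((l_img, "image InfoNCE"), (ce_i, "image CE"), (ce_t, "text CE")):
        if not np.isfinite(part.data):
            raise FloatingPointError(f"non-finite loss component: {name}")
    return LossBundle(float(l_img.data), float(l_sem.data), float(l_clip.data),
                      float(ce_i.data), float(ce_t.data), total)
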
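"""Calibrated nodule- and patient-level risk, fold ensembling, and zero-shot
semantic inference.

Each fold's raw image-branch probabilities are passed through a Beta
calibrator fitted on that fold's validation split, nodule scores are
max-aggregated to the patient, and the per-fold calibrated scores are averaged
into the ensemble risk.  Zero-shot semantic predictions rank a prompt bank by
cosine similarity to the image embedding with a softmax at the learned
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .model import NoduleCLIP, l2_normalize
from .semantics import PromptBank, WhitespaceHashTokenizer

__all__ = [
    "BetaCalibrator", "predict_nodule", "aggregate_patient",
    "fit_beta_calibrator", "ensemble", "zero_shot_infer", "ZeroShotResult",
    "patient_scores",
]

_EPS = 1e-6


# ------------------------------------------------------------- risk scores
def predict_nodule(model: NoduleCLIP, views: np.ndarray) -> float:
    """Positive-class probability of the image branch for one view stack."""
    views = np.asarray(views)
    if views.ndim == 4:
        views = views[None]
    logits = model.eval().image_logits(views)[0]
    z = logits - logits.max()
    e = np.exp(z)
    return float(e[1] / e.sum())


def aggregate_patient(nodule_probs) -> float:
    """Patient-level risk = maximum over the patient's nodule probabilities."""
    probs = np.asarray(nodule_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("patient has no nodule scores")
    return float(probs.max())


# -------------------------------------------------------- Beta calibration
@dataclass
class BetaCalibrator:
    """Three-parameter Beta calibration map
    mu(p) = sigmoid(c + a*ln p - b*ln(1-p)), monotone for a, b >= 0.
    (a, b, c) = (1, 1, 0) is the identity."""

    a: float = 1.0
    b: float = 1.0
    c: float = 0.0

    def __post_init__(self):
        if self.a < 0 or self.b < 0:
            raise ValueError("a and b must be non-negative for monotonicity")

    def __call__(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        scalar = p.ndim == 0
        p = np.atleast_1d(p)
        out = np.empty_like(p)
        inner = (p > 0) & (p < 1)
        q = np.clip(p[inner], _EPS, 1 - _EPS)
        z = self.c + self.a * np.log(q) - self.b * np.log1p(-q)
        out[inner] = 1.0 / (1.0 + np.exp(-z))
        out[p <= 0] = 0.0 if self.a > 0 else 1.0 / (1.0 + np.exp(-self.c))
        out[p >= 1] = 1.0 if self.b > 0 else 1.0 / (1.0 + np.exp(-self.c))
        return float(out[0]) if scalar else out

    calibrate = __call__


def fit_beta_calibrator(probs, labels) -> BetaCalibrator:
    """Fit (a, b, c) by logistic regression of the labels on
    (ln p, -ln(1-p)), with non-negativity enforced by refitting without any
    feature whose coefficient comes out negative."""
    from sklearn.linear_model import LogisticRegression

    probs = np.clip(np.asarray(probs, dtype=float), _EPS, 1 - _EPS)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("calibration requires both classes")
    features = np.column_stack([np.log(probs), -np.log1p(-probs)])

    def _fit(cols: list[int]) -> tuple[np.ndarray, float]:
        lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        lr.fit(features[:, cols], labels)
        coef = np.zeros(2)
        coef[cols] = lr.coef_[0]
        return coef, float(lr.intercept_[0])

    coef, intercept = _fit([0, 1])
    if coef[0] < 0:
        coef, intercept = _fit([1])
    elif coef[1] < 0:
        coef, intercept = _fit([0])
    return BetaCalibrator(a=max(coef[0], 0.0), b=max(coef[1], 0.0), c=intercept)


def ensemble(per_fold_scores, expected: int = 5) -> np.ndarray | float:
    """Average the calibrated per-fold predictions.

    ``per_fold_scores`` is a sequence with one entry (scalar or array) per
    fold model; ``expected`` enforces the fold count (5 in the standard
    five-fold protocol)."""
    scores = [np.asarray(s, dtype=float) for s in per_fold_scores]
    if len(scores) != expected:
        raise ValueError(f"expected {expected} fold predictions, got {len(scores)}")
    out = np.mean(np.stack(scores), axis=0)
    return float(out) if out.ndim == 0 else out


def patient_scores(nodule_probs: np.ndarray, patient_ids) -> dict[str, float]:
    """Max-aggregate nodule probabilities per patient."""
    out: dict[str, list[float]] = {}
    for p, pid in zip(np.asarray(nodule_probs, dtype=float), patient_ids):
        out.setdefault(str(pid), []).append(float(p))
    return {pid: aggregate_patient(v) for pid, v in out.items()}


# ---------------------------------------------------------------- zero-shot
@dataclass
class ZeroShotResult:
    """Per-feature zero-shot predictions: class probability maps for
    (multi-)categorical features, presence probabilities for binaries."""

    categorical: dict   # feature -> {class: probability}
    binary: dict        # feature -> presence probability


def zero_shot_infer(model: NoduleCLIP, views: np.ndarray, bank: PromptBank,
                    tokenizer=None) -> ZeroShotResult:
    """Softmax over cosine similarities between the image embedding and each
    feature's prompt embeddings, at the learned temperature."""
    model.eval()
    tokenizer = tokenizer or WhitespaceHashTokenizer(
        vocab_size=model.cfg.vocab_size, context_length=model.cfg.context_length)
    views = np.asarray(views)
    if views.ndim == 4:
        views = views[None]

    prompts: list[str] = []
    slots: list[tuple[str, str, object]] = []
    for feat, entries in bank.categorical.items():
        if not entries:
            raise ValueError(f"empty prompt set for feature {feat}")
        for cls, sentence in entries:
            slots.append(("categorical", feat, cls))
            prompts.append(sentence)
    for feat, (pos, neg) in bank.binary.items():
        slots.append(("binary", feat, True))
        prompts.append(pos)
        slots.append(("binary", feat, False))
        prompts.append(neg)
    if not prompts:
        raise ValueError("empty prompt bank")

    with nn.no_grad():
        z, _ = model.encode_views(views)
        img = l2_normalize(model.img_proj(z)).data[0]
        tokens, eots = tokenizer.encode_batch(prompts)
        txt = l2_normalize(model.txt_proj(model.encode_text(tokens, eots))).data
    sims = txt @ img
    tau = float(np.clip(model.tau.data, 1e-3, None))

    def _softmax(x):
        z = x / tau
        z = z - z.max()
        e = np.exp(z)
        return e / e.sum()

    categorical: dict = {}
    binary: dict = {}
    pos = 0
    for feat, entries in bank.categorical.items():
        k = len(entries)
        probs = _softmax(sims[pos:pos + k])
        categorical[feat] = {cls: float(p) for (cls, _), p in zip(entries, probs)}
        pos += k
    for feat in bank.binary:
        probs = _softmax(sims[pos:pos + 2])
        binary[feat] = float(probs[0])
        pos += 2
    return ZeroShotResult(categorical, binary)
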
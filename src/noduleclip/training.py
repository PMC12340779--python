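"""Patient-level splitting, rarity-upsampling sampling, the optimization loop,
and five-fold model production.

Splits are patient-disjoint: a 20% held-out test set, then 5-fold
cross-validation with an 80/20 train/validation partition of the remainder.
Batches are drawn with replacement, weighted so that nodules carrying rare
semantic-feature values are upsampled.  Each fold trains the full objective
(symmetric InfoNCE + two class-weighted cross-entropies, equally weighted)
with AdamW, selects the epoch with the best validation AUROC of the image
branch, and the five fold checkpoints feed the calibrated ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .imaging import (AugmentationPolicy, augment_crop, crop_and_normalize,
                      extract_nine_views, load_volume, read_manifest,
                      resample_isotropic, to_view_stack)
from .metrics import auroc
from .model import (LoRAConfig, NoduleCLIP, build_model, compute_losses,
                    inject_lora)
from .semantics import (ReportText, SemanticRecord, SemanticSchema,
                        TextAugPolicy, WhitespaceHashTokenizer, augment_text,
                        default_schema, render_report, select_training_text)

__all__ = [
    "SplitPlan", "TrainConfig", "SamplerPolicy", "NoduleDataset", "FoldResult",
    "make_splits", "compute_sample_weights", "inverse_frequency_class_weights",
    "train_fold", "train_all_folds", "predict_probs",
]


# ------------------------------------------------------------------- splits
@dataclass
class SplitPlan:
    test_patients: list[str]
    folds: list[dict]  # each {"train": [...], "val": [...]}

    def audit(self) -> None:
        test = set(self.test_patients)
        for k, fold in enumerate(self.folds):
            train, val = set(fold["train"]), set(fold["val"])
            if train & val:
                raise ValueError(f"fold {k}: train/val share patients")
            if (train | val) & test:
                raise ValueError(f"fold {k}: test patients leak into the fold")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"test_patients": self.test_patients, "folds": self.folds},
                      fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["test_patients"], d["folds"])


def make_splits(patient_ids, seed: int, n_folds: int = 5,
                test_frac: float = 0.2) -> SplitPlan:
    """Deterministic patient-level split: ``test_frac`` held out, the rest
    partitioned into ``n_folds`` disjoint validation chunks (so each fold
    trains on (n_folds-1)/n_folds of the development patients)."""
    patients = sorted(set(map(str, patient_ids)))
    if len(patients) < n_folds:
        raise ValueError("need at least as many patients as folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(patients))
    n_test = int(round(test_frac * len(order)))
    test = sorted(order[:n_test])
    dev = order[n_test:]
    chunks = [sorted(c) for c in np.array_split(dev, n_folds)]
    folds = []
    for k in range(n_folds):
        val = chunks[k]
        train = sorted(p for c in chunks[:k] + chunks[k + 1:] for p in c)
        folds.append({"train": train, "val": val})
    plan = SplitPlan(test, folds)
    plan.audit()
    return plan


# ------------------------------------------------------------------ sampler
@dataclass
class SamplerPolicy:
    """Rarity upsampling: a nodule's weight is the inverse frequency of its
    rarest non-missing semantic value, floored to avoid single-exemplar
    explosion, then mean-normalized."""

    frequency_floor: float = 0.005

    def __post_init__(self):
        if not 0 < self.frequency_floor < 1:
            raise ValueError("frequency floor must lie in (0, 1)")


def compute_sample_weights(records: list[SemanticRecord],
                           policy: SamplerPolicy | None = None,
                           schema: SemanticSchema | None = None) -> np.ndarray:
    if not records:
        raise ValueError("no records")
    policy = policy or SamplerPolicy()
    schema = schema or default_schema()

    def values_of(rec: SemanticRecord):
        for f in schema:
            v = rec.get(f.name)
            if v is None:
                continue
            if f.kind == "multilabel":
                for c in v:
                    yield (f.name, c)
            else:
                yield (f.name, v)

    counts: dict = {}
    for rec in records:
        for key in values_of(rec):
            counts[key] = counts.get(key, 0) + 1
    n = len(records)
    weights = np.empty(n)
    for i, rec in enumerate(records):
        freqs = [max(counts[k] / n, policy.frequency_floor) for k in values_of(rec)]
        weights[i] = max(1.0 / f for f in freqs) if freqs else 1.0
    return weights / weights.mean()


def inverse_frequency_class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse class-frequency weights, normalized to mean 1 (the malignant
    minority class receives the higher weight)."""
    labels = np.asarray(labels).astype(int)
    freqs = np.array([(labels == c).mean() for c in (0, 1)])
    if np.any(freqs == 0):
        return np.ones(2)
    w = 1.0 / freqs
    return w / w.mean()


# ------------------------------------------------------------------ dataset
@dataclass
class NoduleDataset:
    """Preprocessed cohort: per-nodule view stacks, rendered reports, labels
    and patient ids, ready for batching."""

    view_stacks: np.ndarray          # (N, 9, 3, S, S)
    reports: list[ReportText]
    labels: np.ndarray               # (N,)
    patient_ids: list[str]
    nodule_ids: list[str]
    records: list[SemanticRecord]

    def __len__(self):
        return len(self.labels)

    def indices_for_patients(self, patients) -> np.ndarray:
        wanted = set(patients)
        return np.array([i for i, p in enumerate(self.patient_ids) if p in wanted],
                        dtype=int)

    @classmethod
    def from_cases(cls, cases, image_size: int,
                   augment: AugmentationPolicy | None = None,
                   rng: np.random.Generator | None = None,
                   schema: SemanticSchema | None = None) -> "NoduleDataset":
        """Preprocess in-memory phantom cases (volumes already 1 mm isotropic
        are cropped directly; otherwise they are resampled first)."""
        schema = schema or default_schema()
        stacks, reports, labels, pids, nids, recs = [], [], [], [], [], []
        for case in cases:
            vol = case.volume
            if not np.allclose(vol.spacing, 1.0):
                vol = resample_isotropic(vol)
            if augment is not None:
                crop = augment_crop(vol, case.centroid_mm, augment, rng)
            else:
                crop = crop_and_normalize(vol, case.centroid_mm)
            planes, frames = extract_nine_views(crop)
            stacks.append(to_view_stack(planes, frames, out_size=image_size).views)
            reports.append(render_report(case.record, schema))
            labels.append(case.label)
            pids.append(case.record.patient_id)
            nids.append(case.record.nodule_id)
            recs.append(case.record)
        return cls(np.stack(stacks), reports, np.asarray(labels, dtype=int),
                   pids, nids, recs)

    @classmethod
    def from_files(cls, manifest_path, records: list[SemanticRecord],
                   image_size: int, root=None,
                   schema: SemanticSchema | None = None) -> "NoduleDataset":
        from pathlib import Path

        manifest = read_manifest(manifest_path)
        root = Path(root) if root is not None else Path(manifest_path).parent
        by_key = {(r.patient_id, r.nodule_id): r for r in records}

        class _Case:
            pass

        cases = []
        for _, row in manifest.iterrows():
            case = _Case()
            case.volume = resample_isotropic(load_volume(root / row["image_path"]))
            case.centroid_mm = np.array([row["x_mm"], row["y_mm"], row["z_mm"]])
            key = (str(row["patient_id"]), str(row["nodule_id"]))
            case.record = by_key.get(key, SemanticRecord(*key, {}))
            case.label = int(row["label"])
            cases.append(case)
        return cls.from_cases(cases, image_size, schema=schema)


# ----------------------------------------------------------------- training
@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.1
    batch_size: int = 16
    tau_init: float = 0.03
    epochs: int = 100
    patience: int = 10
    seed: int = 0
    tuning: str = "full"             # "full" | "lora" | "probe"
    lora: LoRAConfig = field(default_factory=LoRAConfig)
    preset: str | object = "tiny"
    text_aug: TextAugPolicy | None = field(default_factory=TextAugPolicy)
    sampler: SamplerPolicy = field(default_factory=SamplerPolicy)
    # train-time view augmentation: "none" | "flip" | "dihedral"; flips are
    # the in-plane realization of the volumetric flip augmentation, dihedral
    # additionally composes right-angle rotations (cube symmetries)
    view_aug: str = "flip"
    view_noise_sd: float = 0.0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 2:
            raise ValueError("contrastive training needs batch_size >= 2 "
                             "(in-batch negatives)")
        if self.view_aug not in ("none", "flip", "dihedral"):
            raise ValueError(f"unknown view_aug mode {self.view_aug!r}")


def augment_views(views: np.ndarray, rng: np.random.Generator, mode: str,
                  noise_sd: float = 0.0) -> np.ndarray:
    """Per-view dihedral/flip augmentation plus optional fresh pixel noise.

    Operates on standardized (B, 9, 3, S, S) batches; flips and right-angle
    rotations are exact symmetries of the cubic crop, so they stay within the
    distribution the nine-view extractor produces.
    """
    if mode == "none" and noise_sd <= 0:
        return views
    out = views.copy()
    b, k = out.shape[0], out.shape[1]
    for i in range(b):
        for j in range(k):
            if mode == "flip":
                if rng.random() < 0.5:
                    out[i, j] = out[i, j][:, ::-1, :]
                if rng.random() < 0.5:
                    out[i, j] = out[i, j][:, :, ::-1]
            elif mode == "dihedral":
                r = int(rng.integers(0, 8))
                img = np.rot90(out[i, j], r % 4, axes=(1, 2))
                if r >= 4:
                    img = img[:, ::-1, :]
                out[i, j] = img
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, out.shape).astype(out.dtype)
    return out


@dataclass
class FoldResult:
    state: dict
    log: list[dict]
    best_epoch: int
    best_val_auroc: float


def _make_fold_model(cfg: TrainConfig, seed: int) -> NoduleCLIP:
    model = build_model(cfg.preset, seed=seed, tau_init=cfg.tau_init)
    if cfg.tuning == "lora":
        inject_lora(model, cfg.lora, seed=seed + 1)
    elif cfg.tuning == "probe":
        nn.freeze(model.vision)
        nn.freeze(model.text)
    elif cfg.tuning != "full":
        raise ValueError(f"unknown tuning mode {cfg.tuning!r}")
    return model


def _batch_texts(dataset: NoduleDataset, idx: np.ndarray, cfg: TrainConfig,
                 rng: np.random.Generator, protected: set[str]) -> list[str]:
    texts = []
    for i in idx:
        sentences = select_training_text(dataset.reports[i], rng)
        if cfg.text_aug is not None:
            sentences = augment_text(sentences, cfg.text_aug, rng, protected)
        texts.append(" ".join(sentences))
    return texts


def predict_probs(model: NoduleCLIP, view_stacks: np.ndarray,
                  batch: int = 64) -> np.ndarray:
    """Positive-class probability of the image branch, batched, eval mode."""
    model.eval()
    out = []
    for lo in range(0, len(view_stacks), batch):
        logits = model.image_logits(view_stacks[lo:lo + batch])
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        out.append((e[:, 1] / e.sum(axis=1)))
    return np.concatenate(out)


def train_fold(dataset: NoduleDataset, train_idx, val_idx, cfg: TrainConfig,
               model: NoduleCLIP | None = None, seed: int | None = None,
               tokenizer=None) -> FoldResult:
    """Train one fold; returns the best-validation-AUROC checkpoint and the
    per-epoch log of every loss component."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    train_idx = np.asarray(train_idx, dtype=int)
    val_idx = np.asarray(val_idx, dtype=int)
    if set(dataset.patient_ids[i] for i in train_idx) & \
            set(dataset.patient_ids[i] for i in val_idx):
        raise ValueError("fold is not patient-disjoint")

    model = model if model is not None else _make_fold_model(cfg, seed)
    tokenizer = tokenizer or WhitespaceHashTokenizer(
        vocab_size=model.cfg.vocab_size, context_length=model.cfg.context_length)
    schema = default_schema()
    protected = schema.class_vocabulary()

    train_records = [dataset.records[i] for i in train_idx]
    weights = compute_sample_weights(train_records, cfg.sampler, schema)
    p_sample = weights / weights.sum()
    class_w = inverse_frequency_class_weights(dataset.labels[train_idx])
    for mod in model.modules():
        if isinstance(mod, nn.LoRALinear):
            mod.rng = rng

    opt = nn.AdamW([p for p in model.parameters() if p.requires_grad],
                   lr=cfg.lr, weight_decay=cfg.weight_decay)
    steps = int(np.ceil(len(train_idx) / cfg.batch_size))
    best_state, best_auroc, best_epoch = model.state_dict(), -np.inf, -1
    log: list[dict] = []
    val_labels = dataset.labels[val_idx]
    for epoch in range(cfg.epochs):
        model.train()
        epoch_losses = {"l_img": 0.0, "l_sem": 0.0, "l_clip": 0.0,
                        "ce_img": 0.0, "ce_txt": 0.0, "total": 0.0}
        for _ in range(steps):
            idx = rng.choice(train_idx, size=cfg.batch_size, replace=True,
                             p=p_sample)
            texts = _batch_texts(dataset, idx, cfg, rng, protected)
            tokens, eots = tokenizer.encode_batch(texts)
            views = augment_views(dataset.view_stacks[idx], rng, cfg.view_aug,
                                  cfg.view_noise_sd)
            bundle = compute_losses(model, views, tokens,
                                    eots, dataset.labels[idx], class_w)
            opt.zero_grad()
            bundle.total_tensor.backward()
            opt.step()
            with nn.no_grad():
                model.clamp_tau()
            for k in epoch_losses:
                epoch_losses[k] += getattr(bundle, k) if k != "total" else bundle.total
        for k in epoch_losses:
            epoch_losses[k] /= steps

        val_probs = predict_probs(model, dataset.view_stacks[val_idx])
        val_auroc = auroc(val_probs, val_labels) if val_labels.min() != val_labels.max() else float("nan")
        log.append(dict(epoch=epoch, **epoch_losses, val_auroc=val_auroc,
                        tau=float(model.tau.data)))
        if np.isfinite(val_auroc) and val_auroc > best_auroc:
            best_auroc, best_epoch = val_auroc, epoch
            best_state = model.state_dict()
        if epoch - best_epoch >= cfg.patience:
            break
    model.load_state_dict(best_state)
    return FoldResult(best_state, log, best_epoch, float(best_auroc))


def train_all_folds(plan: SplitPlan, dataset: NoduleDataset, cfg: TrainConfig,
                    n_folds: int | None = None) -> list[FoldResult]:
    """Train every fold of the plan with independent seeds derived from the
    master seed; returns one checkpoint per fold."""
    plan.audit()
    folds = plan.folds if n_folds is None else plan.folds[:n_folds]
    children = np.random.SeedSequence(cfg.seed).spawn(len(folds))
    results = []
    for fold, ss in zip(folds, children):
        seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        result = train_fold(dataset,
                            dataset.indices_for_patients(fold["train"]),
                            dataset.indices_for_patients(fold["val"]),
                            cfg, seed=seed)
        results.append(result)
    return results
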
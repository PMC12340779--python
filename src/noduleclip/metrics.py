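"""Discrimination metrics, bootstrap confidence intervals, operating points at
fixed recall, and cross-fold statistical comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

__all__ = [
    "auroc", "auprc", "bootstrap_ci", "metrics_at_recall", "weighted_auroc",
    "fold_statistics", "FoldComparison", "expected_calibration_error",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic (ties count 1/2)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision (step-wise integral of precision over recall)."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise ValueError("average precision requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_ci(scores, labels, metric=auroc, n_boot: int = 10000,
                 seed: int | None = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI over resampled (score, label) pairs.

    Resamples lacking one of the classes are redrawn.  The resampling unit is
    the row — pass patient-level scores for a patient-level interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    metric(scores, labels)  # must be computable on the full sample
    rng = np.random.default_rng(seed)
    n = scores.size
    vals = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.min() != lab.max():
                break
        vals[b] = metric(scores[idx], lab)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def metrics_at_recall(scores, labels,
                      targets=(0.6, 0.7, 0.8, 0.9)) -> dict[float, dict[str, float]]:
    """FPR and precision at the observed-score threshold whose recall is
    closest to each target (ties resolved toward higher recall — the
    screening-sensitivity convention)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    out = {}
    thresholds = np.unique(scores)
    ops = []
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        recall = tp / n_pos
        fpr = fp / n_neg
        precision = tp / max(tp + fp, 1)
        ops.append((recall, fpr, precision))
    for target in targets:
        # closest recall; ties toward higher recall, then fewer false positives
        best = min(ops, key=lambda op: (abs(op[0] - target), -op[0], op[1]))
        out[target] = {"recall": best[0], "fpr": best[1], "precision": best[2]}
    return out


def weighted_auroc(class_probs, class_labels, classes=None) -> float:
    """One-vs-rest AUROC per class, averaged with prevalence weights.

    ``class_probs``: (n, k) scores, one column per entry of ``classes`` (which
    defaults to integer column indices).  Classes absent from the labels are
    skipped; a class observed in every label cannot be ranked and is likewise
    skipped, though it still consumes prevalence weight.
    """
    class_probs = np.asarray(class_probs, dtype=float)
    labels = np.asarray(class_labels)
    if classes is None:
        classes = list(range(class_probs.shape[1]))
    observed = [c for c in classes if np.any(labels == c)]
    if len(observed) < 2:
        raise ValueError("need at least two observed classes")
    total = labels.size
    score = 0.0
    for col, c in enumerate(classes):
        y = (labels == c).astype(int)
        if y.min() == y.max():
            continue
        score += (y.sum() / total) * auroc(class_probs[:, col], y)
    return float(score)


@dataclass
class FoldComparison:
    """Cross-fold comparison of >= 2 systems on aligned folds."""

    systems: list[str]
    friedman_stat: float | None
    friedman_p: float | None
    nemenyi_p: np.ndarray | None        # pairwise p-value matrix
    wilcoxon_p: dict                    # (sys_a, sys_b) -> p
    t_ci: dict                          # system -> (mean, lo, hi)


def _nemenyi(ranks: np.ndarray) -> np.ndarray:
    """Pairwise Nemenyi p-values from per-fold ranks (n folds x k systems)."""
    n, k = ranks.shape
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2)
            pv = float(stats.studentized_range.sf(q, k, np.inf))
            p[i, j] = p[j, i] = min(1.0, pv)
    return p


def fold_statistics(per_fold_metrics: dict[str, np.ndarray],
                    alpha: float = 0.05) -> FoldComparison:
    """Friedman test (>= 3 systems) with post-hoc Nemenyi, Wilcoxon
    signed-rank for each pair, and per-system t-based CIs
    (mean +/- t_{1-alpha/2, n-1} * sd / sqrt(n))."""
    systems = list(per_fold_metrics)
    arrays = [np.asarray(per_fold_metrics[s], dtype=float) for s in systems]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("folds are misaligned across systems")
    if len(systems) < 2:
        raise ValueError("need at least two systems")

    friedman_stat = friedman_p = None
    nemenyi_p = None
    if len(systems) >= 3:
        if all(np.allclose(a, arrays[0]) for a in arrays[1:]):
            friedman_stat, friedman_p = 0.0, 1.0
        else:
            friedman_stat, friedman_p = stats.friedmanchisquare(*arrays)
        mat = np.column_stack(arrays)
        ranks = np.apply_along_axis(stats.rankdata, 1, mat)
        nemenyi_p = _nemenyi(ranks)

    wilcoxon_p = {}
    for i, a in enumerate(systems):
        for j in range(i + 1, len(systems)):
            b = systems[j]
            diff = arrays[i] - arrays[j]
            if np.allclose(diff, 0):
                wilcoxon_p[(a, b)] = 1.0
            else:
                wilcoxon_p[(a, b)] = float(
                    stats.wilcoxon(arrays[i], arrays[j], zero_method="wilcox").pvalue)

    t_ci = {}
    tq = stats.t.ppf(1 - alpha / 2, df=n - 1)
    for s, a in zip(systems, arrays):
        half = tq * a.std(ddof=1) / np.sqrt(n)
        t_ci[s] = (float(a.mean()), float(a.mean() - half), float(a.mean() + half))
    return FoldComparison(systems, friedman_stat, friedman_p, nemenyi_p,
                          wilcoxon_p, t_ci)


def expected_calibration_error(probs, labels, n_bins: int = 10) -> float:
    """Standard equal-width-bin ECE estimate."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        m = which == b
        if m.any():
            ece += m.mean() * abs(probs[m].mean() - labels[m].mean())
    return float(ece)
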
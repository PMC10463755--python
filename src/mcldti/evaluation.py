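"""Ranking metrics, multi-run aggregation and ablation configurations.

ROC-AUC follows the Mann-Whitney convention (ties get half credit);
PR-AUC is average precision with step integration and tied scores
grouped, which avoids the optimism of trapezoidal interpolation.  Both
are implemented directly so they can be verified against brute-force
pair-counting oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import ModelConfig


class UndefinedMetricError(ValueError):
    pass


def _check(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equally long")
    return scores, labels


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Equals the fraction of (positive, negative) pairs ranked correctly,
    with ties counted half.
    """
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC-AUC needs both classes present")
    ranks = _midranks(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(scores, labels) -> float:
    """Average precision: sum of precision at each recall step.

    Scores are sorted descending; tied scores form a single threshold
    group, so the result is invariant to the input order.
    """
    scores, labels = _check(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("PR-AUC needs at least one positive")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        group_tp = int(y[i:j + 1].sum())
        group_fp = (j - i + 1) - group_tp
        tp += group_tp
        fp += group_fp
        precision = tp / (tp + fp)
        ap += precision * (group_tp / n_pos)
        i = j + 1
    return float(ap)


def recall_f1(scores, labels, threshold: float = 0.5):
    """(recall, F1) at a hard decision threshold on the scores."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    scores, labels = _check(scores, labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return float(recall), float(f1)


METRICS = ("roc_auc", "pr_auc", "recall", "f1")


def compute_metrics(scores, labels, threshold: float = 0.5) -> dict:
    rec, f1 = recall_f1(scores, labels, threshold)
    return {"roc_auc": roc_auc(scores, labels),
            "pr_auc": pr_auc(scores, labels),
            "recall": rec, "f1": f1}


@dataclass
class MetricsReport:
    """Per-metric mean and sample standard deviation over n runs."""

    mean: dict
    std: dict
    n_runs: int

    def __str__(self) -> str:
        return "  ".join(
            f"{k}: {self.mean[k]:.3f} ± {self.std[k]:.3f}"
            for k in METRICS if k in self.mean)

    @classmethod
    def from_runs(cls, per_run_metrics: list) -> "MetricsReport":
        if not per_run_metrics:
            raise ValueError("need at least one run")
        keys = per_run_metrics[0].keys()
        mean, std = {}, {}
        for k in keys:
            vals = np.array([m[k] for m in per_run_metrics], dtype=float)
            mean[k] = float(vals.mean())
            std[k] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return cls(mean=mean, std=std, n_runs=len(per_run_metrics))


def aggregate_runs(runs) -> MetricsReport:
    """Aggregate (scores, labels) pairs from repeated runs into mean +- std."""
    return MetricsReport.from_runs(
        [compute_metrics(scores, labels) for scores, labels in runs])


#: Ablation variants: config deltas relative to the full model.
ABLATION_VARIANTS = {
    "full": {},
    "image+smiles": {"drug_text_source": "smiles"},
    "text": {"modalities": ("text",)},
    "image": {"modalities": ("image",)},
    "-mca": {"use_mca": False},
    "-mca-image": {"use_mca": False, "modalities": ("text",)},
    "-mca-text": {"use_mca": False, "modalities": ("image",)},
}


def build_ablation(name: str, base: ModelConfig | None = None) -> ModelConfig:
    """Model configuration for a named ablation variant.

    ``-mca-image`` removes cross-attention *and* the image modality
    (text-only drug); ``-mca-text`` removes cross-attention and the text
    modality (image-only drug); ``image+smiles`` feeds raw SMILES
    characters through the text channel instead of the chemical text.
    """
    if name not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown ablation {name!r}; choose from {sorted(ABLATION_VARIANTS)}")
    base = base or ModelConfig()
    return replace(base, **ABLATION_VARIANTS[name])
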
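"""Threshold-free multilabel metrics: per-class and macro AUPRC / AUROC.

AUROC is computed as the normalized Mann-Whitney U statistic (probability
that a random positive outscores a random negative, ties counted half).
AUPRC is average precision — the step-wise integral of the precision-recall
curve, i.e. the mean of the precision evaluated at each positive in
score-descending order, ties broken by stable input order.

A class enters the macro averages only if the evaluation set contains at
least one positive and one negative for it; non-evaluable classes are
excluded (with their count reported) rather than given an arbitrary value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    per_class_auprc: dict = field(default_factory=dict)
    per_class_auroc: dict = field(default_factory=dict)
    macro_auprc: float = float("nan")
    macro_auroc: float = float("nan")
    n_evaluable_classes: int = 0
    non_evaluable: list = field(default_factory=list)
    challenge_score: float | None = None   # reserved; not computed here

    def to_dict(self) -> dict:
        return {
            "macro_auprc": self.macro_auprc,
            "macro_auroc": self.macro_auroc,
            "n_evaluable_classes": self.n_evaluable_classes,
            "non_evaluable": list(self.non_evaluable),
            "per_class_auprc": dict(self.per_class_auprc),
            "per_class_auroc": dict(self.per_class_auroc),
            "challenge_score": self.challenge_score,
        }


def auroc(scores, labels) -> float:
    """Rank-based AUROC; requires >= 1 positive and >= 1 negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both a positive and a negative")
    ranks = rankdata(scores)               # average ranks: ties count half
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Average precision; requires >= 1 positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    if n_pos == 0:
        raise ValueError("AUPRC needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    precision = tp / np.arange(1, len(scores) + 1)
    return float(precision[sorted_labels].sum() / n_pos)


def macro_metrics(scores: np.ndarray, labels: np.ndarray,
                  class_names: list[str] | None = None) -> EvalResult:
    """Unweighted per-class means of AUPRC and AUROC over evaluable classes.

    ``scores`` and ``labels`` are [n_samples, n_classes]; labels are binary.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = np.atleast_2d(np.asarray(labels))
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have matching shapes")
    k = scores.shape[1]
    names = class_names or [str(i) for i in range(k)]
    result = EvalResult()
    for j in range(k):
        col = labels[:, j].astype(bool)
        if col.all() or not col.any():
            result.non_evaluable.append(names[j])
            continue
        result.per_class_auroc[names[j]] = auroc(scores[:, j], col)
        result.per_class_auprc[names[j]] = auprc(scores[:, j], col)
    result.n_evaluable_classes = len(result.per_class_auroc)
    if result.n_evaluable_classes:
        result.macro_auroc = float(
            np.mean(list(result.per_class_auroc.values())))
        result.macro_auprc = float(
            np.mean(list(result.per_class_auprc.values())))
    if result.non_evaluable:
        logger.info("%d class(es) excluded from macro averages: %s",
                    len(result.non_evaluable),
                    ",".join(result.non_evaluable))
    return result
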
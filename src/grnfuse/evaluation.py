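"""Scoring predicted networks against a reference network.

Matching is direction-blind: a predicted edge counts as a true positive if
the reference contains the pair in either orientation.  Threshold-free
ranking quality is summarized by AUROC (midrank Mann-Whitney form, robust
to the heavy score ties produced by thresholded matrices) and AUPR (step
interpolation over all thresholds).  The negative universe for ranking is
every unordered gene pair absent from the reference (self-pairs excluded),
optionally minus an exclusion list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .io_formats import EdgeList, ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationReport",
    "confusion_counts",
    "prf1",
    "ranking_curves",
    "significance_group",
    "evaluate_network",
]


@dataclass
class EvaluationReport:
    """Confusion counts and summary metrics for one predicted network."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    auroc: float | None = None
    aupr: float | None = None

    def as_dict(self) -> dict:
        return {
            "TP": self.tp, "FP": self.fp, "FN": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "auroc": self.auroc, "aupr": self.aupr,
        }


def confusion_counts(predicted: EdgeList, truth: EdgeList) -> tuple[int, int, int]:
    """TP/FP/FN on unordered pairs (duplicates collapsed, direction ignored)."""
    p = predicted.pairs()
    t = truth.pairs()
    tp = len(p & t)
    return tp, len(p - t), len(t - p)


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from confusion counts (fractions in [0, 1])."""
    if min(tp, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fp == 0:
        logger.warning("no predicted edges: precision undefined, reported 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("empty reference: recall undefined, reported 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _pair_scores_labels(
    scores: ScoredNetwork,
    truth: EdgeList,
    exclude: set[frozenset] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    if not scores.symmetric:
        raise ValueError("ranking expects a symmetric score matrix")
    idx = {g: i for i, g in enumerate(scores.gene_ids)}
    positives = truth.pairs()
    y, s = [], []
    n = len(scores.gene_ids)
    for i in range(n):
        for j in range(i + 1, n):
            pair = frozenset((scores.gene_ids[i], scores.gene_ids[j]))
            if exclude and pair in exclude:
                continue
            y.append(1 if pair in positives else 0)
            s.append(scores.scores[i, j])
    return np.asarray(y), np.asarray(s)


def ranking_curves(
    scores: ScoredNetwork,
    truth: EdgeList,
    exclude: set[frozenset] | None = None,
) -> tuple[float, float]:
    """(AUROC, AUPR) of the pairwise scores against the reference edges."""
    y, s = _pair_scores_labels(scores, truth, exclude)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError("reference must induce both positive and negative pairs")
    return float(roc_auc_score(y, s)), float(average_precision_score(y, s))


@dataclass
class SignificanceGrouping:
    """Top group of statistically indistinguishable best methods."""

    top_group: list[str]
    others: list[str]
    p_value: float | None
    t_statistic: float | None


def significance_group(
    metric_samples: dict[str, list[float]], alpha: float = 0.05
) -> SignificanceGrouping:
    """Group the best-mean method with any peers it cannot be told apart from.

    Methods are ordered by mean; successive unpaired t-tests (Student,
    equal variance) pool the next-best method into the top group while the
    difference is not significant at ``alpha``.  The reported p-value
    compares the pooled top group against the pooled remainder.  Degenerate
    zero-variance inputs fall back to exact-equality grouping.
    """
    if any(len(v) < 2 for v in metric_samples.values()):
        raise ValueError("need at least 2 samples per method")
    names = sorted(metric_samples, key=lambda m: -float(np.mean(metric_samples[m])))
    samples = {m: np.asarray(metric_samples[m], dtype=float) for m in names}

    if all(s.std() == 0 for s in samples.values()):
        best = samples[names[0]][0]
        top = [m for m in names if samples[m][0] == best]
        others = [m for m in names if m not in top]
        return SignificanceGrouping(top_group=top, others=others,
                                    p_value=None, t_statistic=None)

    top = [names[0]]
    for nxt in names[1:]:
        pooled = np.concatenate([samples[m] for m in top])
        t, p = stats.ttest_ind(pooled, samples[nxt], equal_var=True)
        if p < alpha:
            break
        top.append(nxt)
    others = [m for m in names if m not in top]
    if others:
        t, p = stats.ttest_ind(
            np.concatenate([samples[m] for m in top]),
            np.concatenate([samples[m] for m in others]),
            equal_var=True,
        )
        return SignificanceGrouping(top, others, float(p), float(t))
    return SignificanceGrouping(top, [], 1.0, 0.0)


def evaluate_network(
    predicted: EdgeList,
    truth: EdgeList,
    scores: ScoredNetwork | None = None,
) -> EvaluationReport:
    """Full report: confusion counts, P/R/F1 and (with scores) AUROC/AUPR."""
    tp, fp, fn = confusion_counts(predicted, truth)
    precision, recall, f1 = prf1(tp, fp, fn)
    auroc = aupr = None
    if scores is not None:
        auroc, aupr = ranking_curves(scores, truth)
    return EvaluationReport(tp=tp, fp=fp, fn=fn, precision=precision,
                            recall=recall, f1=f1, auroc=auroc, aupr=aupr)
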
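"""Ranked-list evaluation: stepped precision-recall and ROC curves.

Curves follow a fixed-decrement threshold sweep: thresholds run from the
maximum score downward in equal steps (0.002 for probabilities and
correlation coefficients, 2 for log2 expression) and a gene counts as a
predicted positive when its score >= threshold.  Both endpoints are
included, so recall always reaches 1; a threshold with zero predicted
positives (undefined precision) is omitted.  Average precision is the
recall-weighted step integral sum_j (R_j - R_{j-1}) * P_j, which does not
depend on the threshold grid and is invariant to monotone transforms of the
score.  ROC AUC is the Mann-Whitney concordance probability (ties = 1/2).

Two reference rankers are included for comparison with the classifier:
the mean gonadal expression level across the time course, and the pairwise
Pearson-correlation ranker over same-type / different-type gene pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .curation import TrainingSet
from .io import average_replicates
from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)

#: decrements used by the published threshold sweeps, per score type
PROBABILITY_STEP = 0.002
LOG2_EXPRESSION_STEP = 2.0
CORRELATION_STEP = 0.002


@dataclass
class CurvePoints:
    """A stepped PR/ROC curve: one row per retained threshold."""

    table: pd.DataFrame  # threshold, tp, fp, fn, tn, precision, recall, fpr
    step: float

    def __len__(self) -> int:
        return len(self.table)

    @property
    def precision(self) -> np.ndarray:
        return self.table["precision"].to_numpy()

    @property
    def recall(self) -> np.ndarray:
        return self.table["recall"].to_numpy()

    @property
    def fpr(self) -> np.ndarray:
        return self.table["fpr"].to_numpy()

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _align(scores: pd.Series, labels: TrainingSet) -> tuple[np.ndarray, np.ndarray]:
    genes = labels.labels.index
    missing = genes.difference(scores.index)
    if len(missing):
        raise KeyError(f"labeled gene(s) without score: {list(missing[:5])}")
    s = scores.loc[genes].to_numpy(dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("non-finite scores")
    return s, labels.labels.to_numpy()


def pr_curve(scores: pd.Series, labels: TrainingSet, step: float) -> CurvePoints:
    """Precision-recall curve from a fixed-decrement threshold sweep.

    Precision = TP / (TP+FP) over genes scoring >= threshold; recall =
    TP / (number of positives).  The sweep runs from max(score) down past
    min(score) so the final point predicts everything (recall = 1 and
    precision = class prevalence, exactly).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    s, y = _align(scores, labels)
    if len(s) == 0:
        raise ValueError("empty label set")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0:
        raise ValueError("no positive labels")

    hi, lo = float(s.max()), float(s.min())
    n_steps = int(math.ceil((hi - lo) / step)) + 1
    thresholds = hi - step * np.arange(n_steps + 1)

    order = np.argsort(-s, kind="stable")
    s_sorted = -np.sort(-s, kind="stable")
    cum_pos = np.cumsum(y[order] == 1)

    # k(t) = #scores >= t, via searchsorted on the descending-sorted scores
    k = np.searchsorted(-s_sorted, -thresholds, side="right")
    rows = []
    for t, kk in zip(thresholds, k):
        if kk == 0:
            continue  # zero predictions: precision undefined, point omitted
        tp = int(cum_pos[kk - 1])
        fp = int(kk - tp)
        rows.append({
            "threshold": float(t), "tp": tp, "fp": fp,
            "fn": n_pos - tp, "tn": n_neg - fp,
            "precision": tp / kk, "recall": tp / n_pos,
            "fpr": fp / n_neg if n_neg else float("nan"),
        })
    return CurvePoints(pd.DataFrame(rows), step)


def precision_at_recall(curve: CurvePoints, target_recall: float) -> float:
    """Precision at the first sweep point whose recall >= ``target_recall``."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    hits = curve.table[curve.table["recall"] >= target_recall]
    if hits.empty:
        raise ValueError(
            f"target recall {target_recall} exceeds curve maximum "
            f"{curve.table['recall'].max()}"
        )
    return float(hits.iloc[0]["precision"])


def average_precision(curve: CurvePoints) -> float:
    """Recall-weighted mean precision: sum (R_j - R_{j-1}) * P_j, R_0 = 0."""
    if len(curve) == 0:
        raise ValueError("empty curve")
    ap, prev_recall = 0.0, 0.0
    for _, row in curve.table.iterrows():
        if row["recall"] > prev_recall:
            ap += (row["recall"] - prev_recall) * row["precision"]
            prev_recall = row["recall"]
    return ap


def roc_auc(
    scores: pd.Series, labels: TrainingSet | pd.Series,
    step: float = PROBABILITY_STEP,
) -> tuple[CurvePoints, float]:
    """ROC curve (threshold sweep) and exact Mann-Whitney AUC.

    AUC is the probability that a random positive outscores a random
    negative, counting ties as 1/2 — independent of the sweep grid.
    """
    if not isinstance(labels, TrainingSet):
        labels = TrainingSet(labels)
    s, y = _align(scores, labels)
    if (y == 1).all() or (y == -1).all():
        raise ValueError("ROC needs both classes")
    curve = pr_curve(scores, labels, step)
    auc = float(roc_auc_score((y == 1).astype(int), s))
    return curve, auc


# ---------------------------------------------------------------------------
# reference rankers
# ---------------------------------------------------------------------------

def expression_level_baseline(
    matrix: ExpressionMatrix,
    labels: TrainingSet,
    step: float = LOG2_EXPRESSION_STEP,
) -> tuple[pd.Series, CurvePoints]:
    """Rank genes by mean log2 gonadal expression across the time course.

    Replicate columns are averaged first; the PR sweep uses a log2
    decrement of ``step`` (default 2).  Also usable with sorted-cell
    isolate matrices in place of the whole-gonad matrix.
    """
    averaged = average_replicates(matrix) if matrix.n_samples > 1 else matrix
    scores = averaged.subset_genes(labels.labels.index).values.mean(axis=1)
    scores.name = "mean_log2_expression"
    return scores, pr_curve(scores, labels, step)


def correlation_pair_baseline(
    matrix: ExpressionMatrix,
    labels: TrainingSet,
    step: float = CORRELATION_STEP,
) -> tuple[pd.DataFrame, CurvePoints]:
    """Rank gene *pairs* by Pearson correlation of their time profiles.

    Every unordered pair of labeled genes is scored by the Pearson r of
    replicate-averaged time-point profiles; a pair is a positive example
    when both genes share a label (both +1 or both -1) and negative
    otherwise.  Pairs involving a zero-variance profile have undefined r
    and are dropped (logged).  Returns the pair table and the PR curve at
    coefficient decrement ``step``.
    """
    averaged = average_replicates(matrix) if matrix.n_samples > 1 else matrix
    if averaged.n_samples < 3:
        raise ValueError("need >= 3 time points for pair correlations")
    genes = labels.labels.index
    if (labels.labels == 1).sum() < 2 or (labels.labels == -1).sum() < 2:
        raise ValueError("need >= 2 genes per class for pair labels")
    profiles = averaged.subset_genes(genes).values.to_numpy(dtype=float)

    sd = profiles.std(axis=1)
    degenerate = set(np.flatnonzero(sd == 0))
    if degenerate:
        log.warning(
            "%d zero-variance profile(s); their pairs dropped", len(degenerate)
        )
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)

    y = labels.labels.to_numpy()
    rows = []
    for i, j in combinations(range(len(genes)), 2):
        if i in degenerate or j in degenerate:
            continue
        r = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
        rows.append({
            "gene_a": genes[i], "gene_b": genes[j],
            "correlation": r, "label": 1 if y[i] == y[j] else -1,
        })
    pairs = pd.DataFrame(rows)
    pair_scores = pd.Series(
        pairs["correlation"].to_numpy(),
        index=pairs["gene_a"] + "|" + pairs["gene_b"],
    )
    pair_labels = TrainingSet(pd.Series(
        pairs["label"].to_numpy(), index=pair_scores.index, dtype=int
    ))
    return pairs, pr_curve(pair_scores, pair_labels, step)


def pair_prevalence(labels: TrainingSet) -> float:
    """Fraction of same-type pairs among all unordered labeled-gene pairs.

    This is the random-precision floor of the correlation-pair ranker:
    (C(P,2) + C(Q,2)) / C(P+Q,2) for P positives and Q negatives.
    """
    p, q = labels.n_positive, labels.n_negative
    total = math.comb(p + q, 2)
    if total == 0:
        raise ValueError("need at least two labeled genes")
    return (math.comb(p, 2) + math.comb(q, 2)) / total
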
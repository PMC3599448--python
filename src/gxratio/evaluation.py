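"""Confusion-table metrics, Fisher's exact test, ROC/AUC and report tables.

Reports mirror the three study layouts: per-comparison TP/FN/TN/FP counts,
correct/incorrect (Tc/Ti/TOTAL/%I) blocks for total, training and validation
sets, and a method-by-comparison sensitivity/specificity table.  All reports
are TSV round-trippable via pandas.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero (2.5 -> 3)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclasses.dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclasses.dataclass
class EvalReport:
    """One binary comparison: confusion counts, sens/spec, ROC points, AUC."""

    comparison: str
    confusion: ConfusionTable
    sensitivity: float
    specificity: float
    roc_points: list[tuple[float, float]]
    auc: float


def confusion(predicted_labels: Sequence[str], true_labels: Sequence[str],
              positive_label: str) -> ConfusionTable:
    """Standard binary confusion counts; truth must carry exactly two labels."""
    if len(predicted_labels) != len(true_labels):
        raise ValueError("predicted and true label sequences differ in length")
    labels = sorted(set(true_labels))
    if positive_label not in labels:
        raise ValueError(f"positive label {positive_label!r} absent from truth")
    if len(labels) != 2:
        raise ValueError(f"truth must be binary, found labels {labels}")
    negative_label = next(l for l in labels if l != positive_label)
    bad = sorted(set(predicted_labels) - {positive_label, negative_label})
    if bad:
        raise ValueError(
            f"predicted labels {bad} outside {{{positive_label!r}, {negative_label!r}}}"
        )
    tp = fn = tn = fp = 0
    for pred, true in zip(predicted_labels, true_labels):
        if true == positive_label:
            tp += pred == positive_label
            fn += pred != positive_label
        else:
            tn += pred == negative_label
            fp += pred != negative_label
    return ConfusionTable(tp=tp, fn=fn, tn=tn, fp=fp)


def sens_spec(table: ConfusionTable) -> tuple[float, float]:
    """(sensitivity, specificity) = (tp/(tp+fn), tn/(tn+fp))."""
    if table.tp + table.fn == 0:
        raise ValueError("no true cases: sensitivity undefined")
    if table.tn + table.fp == 0:
        raise ValueError("no true controls: specificity undefined")
    return table.tp / (table.tp + table.fn), table.tn / (table.tn + table.fp)


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables (with the observed
    margins) whose probability does not exceed that of the observed table.
    Comparisons are done on exact integer numerators, so ties from symmetric
    tables are handled without floating-point slop.
    """
    (a, b), (c, d) = ((int(x) for x in row) for row in table)
    if min(a, b, c, d) < 0:
        raise ValueError("fisher_exact requires nonnegative counts")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    # P(k) = C(r1, k) C(r2, c1-k) / C(n, c1): compare integer numerators.
    lo, hi = max(0, c1 - r2), min(r1, c1)
    numers = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    obs = numers[a]
    total = math.comb(n, c1)
    return float(min(1.0, sum(v for v in numers.values() if v <= obs) / total))


def roc_auc(decision_scores: Sequence[float], true_labels: Sequence[str],
            positive_label: str) -> tuple[list[tuple[float, float]], float]:
    """ROC by threshold sweep (ties grouped) and trapezoid AUC.

    The trapezoid AUC over the tie-grouped curve equals the Mann-Whitney
    exceedance probability P(case score > control score) + P(tie)/2.
    """
    scores = np.asarray(decision_scores, dtype=float)
    truth = np.asarray([t == positive_label for t in true_labels])
    n_pos = int(truth.sum())
    n_neg = len(truth) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one case and one control for a ROC curve")
    if np.all(scores == scores[0]):
        logger.warning("constant decision scores: ROC is the chance diagonal, AUC 0.5")
    order = np.argsort(-scores, kind="stable")
    scores_sorted = scores[order]
    truth_sorted = truth[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(scores_sorted):
        j = i
        while j < len(scores_sorted) and scores_sorted[j] == scores_sorted[i]:
            j += 1
        tp += int(truth_sorted[i:j].sum())
        fp += (j - i) - int(truth_sorted[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc)


def evaluate_binary(decision_scores: Sequence[float], predicted_labels: Sequence[str],
                    true_labels: Sequence[str], positive_label: str,
                    comparison: str = "") -> EvalReport:
    """Bundle confusion counts, sens/spec and ROC/AUC for one comparison."""
    table = confusion(predicted_labels, true_labels, positive_label)
    sensitivity, specificity = sens_spec(table)
    points, auc = roc_auc(decision_scores, true_labels, positive_label)
    return EvalReport(comparison=comparison, confusion=table,
                      sensitivity=sensitivity, specificity=specificity,
                      roc_points=points, auc=auc)


def per_class_recall(true_labels: Sequence[str],
                     predicted_labels: Sequence[str]) -> dict[str, float]:
    """Fraction of each true class predicted correctly."""
    out: dict[str, float] = {}
    truth = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    for label in sorted(set(true_labels)):
        mask = truth == label
        out[label] = float((pred[mask] == label).mean())
    return out


# ---------------------------------------------------------------------------
# Report tables

def confusion_report(entries: Mapping[str, ConfusionTable],
                     training_pct: int = 60) -> pd.DataFrame:
    """Per-comparison TP/FN/TN/FP table (one row per binary comparison)."""
    rows = []
    for comparison, t in entries.items():
        rows.append({
            "comparison": comparison, "total_n": t.n, "training_pct": training_pct,
            "TP": t.tp, "FN": t.fn, "TN": t.tn, "FP": t.fp,
        })
    return pd.DataFrame(rows)


def accuracy_blocks(n_correct: int, n_incorrect: int) -> dict[str, int]:
    """One Tc/Ti/TOTAL/%I block; %I rounds half away from zero."""
    total = n_correct + n_incorrect
    if total == 0:
        raise ValueError("empty block")
    return {
        "Tc": n_correct, "Ti": n_incorrect, "TOTAL": total,
        "pct_incorrect": round_half_away(100.0 * n_incorrect / total),
    }


def accuracy_report(entries: Mapping[str, Mapping[str, Mapping[str, int]]]) -> pd.DataFrame:
    """Total/training/validation accuracy table.

    ``entries`` maps comparison name -> {"total"|"training"|"validation":
    block from :func:`accuracy_blocks`}.
    """
    rows = []
    for comparison, blocks in entries.items():
        row: dict[str, object] = {"comparison": comparison}
        for block_name in ("total", "training", "validation"):
            block = blocks[block_name]
            for key in ("Tc", "Ti", "TOTAL", "pct_incorrect"):
                row[f"{block_name}_{key}"] = block[key]
        rows.append(row)
    return pd.DataFrame(rows)


def sens_spec_report(entries: Sequence[tuple[str, str, float, float]]) -> pd.DataFrame:
    """Method-by-comparison sensitivity/specificity table.

    ``entries`` holds (comparison, method, sensitivity, specificity) tuples.
    """
    return pd.DataFrame(entries, columns=["comparison", "method",
                                          "sensitivity", "specificity"])


def roc_frame(points: Sequence[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(points, columns=["fpr", "tpr"])


def write_report(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
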
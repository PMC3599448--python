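"""Per-probe two-group differential expression with Bonferroni correction.

Each probe is compared between every disease cohort and the control cohort
with Welch's unequal-variance t-test on relative expression; p-values are
Bonferroni-corrected over the whole family (probes x disease cohorts, the
most conservative reading) and directions called from group means.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t statistic with Satterthwaite df, two-sided p.

    Returns (t, p) with t signed as mean(x) - mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"need >= 2 observations per group, got {nx} and {ny}")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance; t statistic undefined")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def bonferroni(p_values: Iterable[float], m: int) -> np.ndarray:
    """Multiply each p-value by the family size ``m``, capping at 1."""
    if m < 1:
        raise ValueError(f"family size m must be >= 1, got {m}")
    p = np.asarray(list(p_values), dtype=float)
    if len(p) > m:
        raise ValueError(f"family size m={m} smaller than number of tests {len(p)}")
    return np.minimum(1.0, p * m)


@dataclasses.dataclass(frozen=True)
class DiffResult:
    """One probe-by-disease differential expression call."""

    probe_id: str
    disease_label: str
    fold_direction: str  # "up", "down" or "ns"
    fold_ratio: float    # mean(disease) / mean(control) relative expression
    t_stat: float
    p_raw: float
    p_adjusted: float


def differential_table(expr: ExpressionMatrix, control_label: str = "CTRL",
                       alpha: float = 0.05) -> list[DiffResult]:
    """Welch-test every probe in every disease cohort against the controls.

    The Bonferroni family is (probes tested) x (disease cohorts compared).
    Cohorts with fewer than 2 subjects are skipped with a warning; direction
    comes from the difference of group means of relative expression.
    """
    if control_label not in set(expr.groups.values()):
        raise ValueError(f"control label {control_label!r} absent from data")
    ctrl_mask = expr.group_mask(control_label)
    if ctrl_mask.sum() < 2:
        raise ValueError(f"control group needs >= 2 subjects, has {int(ctrl_mask.sum())}")

    diseases = sorted({g for g in expr.groups.values() if g != control_label})
    usable = []
    for label in diseases:
        if expr.group_mask(label).sum() < 2:
            logger.warning("skipping cohort %s: fewer than 2 subjects", label)
        else:
            usable.append(label)

    m = len(expr.probe_ids) * len(usable)
    results: list[DiffResult] = []
    for label in usable:
        case_mask = expr.group_mask(label)
        for j, probe in enumerate(expr.probe_ids):
            x = expr.levels[case_mask, j]
            y = expr.levels[ctrl_mask, j]
            x = x[np.isfinite(x)]
            y = y[np.isfinite(y)]
            if len(x) < 2 or len(y) < 2:
                logger.warning("skipping probe %s in %s: too few finite levels", probe, label)
                continue
            t, p = welch_t(x, y)
            p_adj = float(min(1.0, p * m))
            if p_adj < alpha:
                direction = "up" if x.mean() > y.mean() else "down"
            else:
                direction = "ns"
            results.append(DiffResult(
                probe_id=probe, disease_label=label, fold_direction=direction,
                fold_ratio=float(x.mean() / y.mean()), t_stat=t,
                p_raw=p, p_adjusted=p_adj,
            ))
    return results


def differential_frame(results: Sequence[DiffResult]) -> pd.DataFrame:
    """Long-format DataFrame of differential calls."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def write_differential_table(results: Sequence[DiffResult], path) -> None:
    """Probe x disease TSV of direction calls plus fold ratios."""
    frame = differential_frame(results)
    if frame.empty:
        pd.DataFrame().to_csv(path, sep="\t")
        return
    direction = frame.pivot(index="probe_id", columns="disease_label",
                            values="fold_direction")
    fold = frame.pivot(index="probe_id", columns="disease_label", values="fold_ratio")
    merged = pd.concat(
        {"direction": direction, "fold_ratio": fold.round(4)}, axis=1
    )
    merged.columns = [f"{label}_{kind}" for kind, label in merged.columns]
    merged.sort_index(axis=1).to_csv(path, sep="\t")
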
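"""The ratioscore method: resampled two-gene ratio search and n-tuple scoring.

The search looks for ordered probe-pair expression ratios on which case
subjects exceed the *maximum* value seen in the control group.  Candidates
are ranked by how often they make the per-resample top list (80% of each
group drawn without replacement, repeated), a small panel is then grown
greedily to cover as many cases as possible on the full training data, and
each subject is scored by counting panel ratios on which it strictly exceeds
the control-max threshold.  A subject is called positive when its score is
at least 1; by construction every training control scores 0.

Thresholds use strict exceedance: the control maximum is itself attained by
a control subject, so an at-or-above rule could never give all controls a
zero score.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True, order=True)
class GeneRatio:
    """Ordered probe pair; A/B and B/A are distinct candidates."""

    numerator_probe: str
    denominator_probe: str

    def __post_init__(self) -> None:
        if self.numerator_probe == self.denominator_probe:
            raise ValueError(f"self-ratio {self.numerator_probe}/{self.denominator_probe}")

    @property
    def name(self) -> str:
        return f"{self.numerator_probe}/{self.denominator_probe}"


@dataclasses.dataclass(frozen=True)
class RatioCandidate:
    ratio: GeneRatio
    separation_count: int
    selection_frequency: float


@dataclasses.dataclass
class RatioPanel:
    """Ordered ratios with per-ratio control-max thresholds (ratio-value units)."""

    ratios: list[GeneRatio]
    thresholds: list[float]
    case_label: str
    control_label: str

    def __post_init__(self) -> None:
        if len(self.ratios) != len(self.thresholds):
            raise ValueError("ratios and thresholds must have equal length")

    def __len__(self) -> int:
        return len(self.ratios)

    @property
    def ratio_names(self) -> list[str]:
        return [r.name for r in self.ratios]

    def to_json(self) -> str:
        return json.dumps({
            "case_label": self.case_label,
            "control_label": self.control_label,
            "ratios": [
                {"numerator": r.numerator_probe, "denominator": r.denominator_probe,
                 "threshold": t}
                for r, t in zip(self.ratios, self.thresholds)
            ],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RatioPanel":
        payload = json.loads(text)
        return cls(
            ratios=[GeneRatio(e["numerator"], e["denominator"]) for e in payload["ratios"]],
            thresholds=[float(e["threshold"]) for e in payload["ratios"]],
            case_label=payload["case_label"],
            control_label=payload["control_label"],
        )


@dataclasses.dataclass(frozen=True)
class ScoreResult:
    """Per-subject binary n-tuple, integer ratioscore and positive/negative call."""

    subject_id: str
    indicator_tuple: tuple[int, ...]
    ratioscore: int
    call: str  # "positive" or "negative"


def separation_count(case_values: Sequence[float], control_values: Sequence[float]) -> int:
    """Number of case values strictly above the control-group maximum."""
    control = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    control = control[np.isfinite(control)]
    if control.size == 0:
        raise ValueError("empty control group: separation threshold undefined")
    if case.size == 0:
        raise ValueError("empty case group")
    return int(np.sum(case > control.max()))


def _ratio_cube(expr: ExpressionMatrix) -> np.ndarray:
    """All pairwise ratio values, shape (n_subjects, p, p); [s, i, j] = lvl_i/lvl_j."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return expr.levels[:, :, None] / expr.levels[:, None, :]


def _group_indices(expr: ExpressionMatrix, label: str) -> np.ndarray:
    idx = np.where(expr.group_mask(label))[0]
    if idx.size == 0:
        raise ValueError(f"no subjects with group label {label!r}")
    return idx


def ratio_values(expr: ExpressionMatrix, ratio: GeneRatio) -> np.ndarray:
    """Ratio value for every subject, in table order."""
    i = expr.probe_index(ratio.numerator_probe)
    j = expr.probe_index(ratio.denominator_probe)
    with np.errstate(invalid="ignore", divide="ignore"):
        return expr.levels[:, i] / expr.levels[:, j]


def search_candidates(expr: ExpressionMatrix, case_label: str, control_label: str,
                      resample_frac: float = 0.80, reps: int = 200,
                      top_k: int = 500, seed: int | None = None,
                      min_frequency: float = 0.0) -> list[RatioCandidate]:
    """Resampled search over all ordered probe-pair ratios.

    Each rep draws ``resample_frac`` of the cases and of the controls without
    replacement (stratified), ranks every ordered pair by its separation count
    within the subsample, and saves the ``top_k`` separating ratios (count > 0,
    ties broken by probe order).  Aggregation across reps yields a selection
    frequency per ratio; candidates are returned sorted by frequency, then
    full-data separation count, then probe-pair order — fully deterministic
    for a fixed seed.
    """
    if seed is None:
        raise ValueError("seed is required; refusing silent nondeterminism")
    if not 0 < resample_frac <= 1:
        raise ValueError("resample_frac must lie in (0, 1]")
    case_idx = _group_indices(expr, case_label)
    ctrl_idx = _group_indices(expr, control_label)
    if case_idx.size < 5 or ctrl_idx.size < 5:
        raise ValueError(
            f"groups too small for resampling: {case_idx.size} cases, "
            f"{ctrl_idx.size} controls (need >= 5 each)"
        )
    p = len(expr.probe_ids)
    cube = _ratio_cube(expr)
    off_diag = ~np.eye(p, dtype=bool)

    rng = np.random.default_rng(seed)
    n_case_s = math.ceil(resample_frac * case_idx.size)
    n_ctrl_s = math.ceil(resample_frac * ctrl_idx.size)
    ii, jj = np.divmod(np.arange(p * p), p)
    hits = np.zeros((p, p), dtype=np.int64)
    for _ in range(reps):
        cs = rng.choice(case_idx, size=n_case_s, replace=False)
        ks = rng.choice(ctrl_idx, size=n_ctrl_s, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ctrl_max = np.nanmax(cube[ks], axis=0)
        counts = np.where(off_diag, (cube[cs] > ctrl_max).sum(axis=0), -1)
        flat = counts.ravel()
        order = np.lexsort((jj, ii, -flat))
        top = order[flat[order] > 0][:top_k]
        hits[ii[top], jj[top]] += 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full_ctrl_max = np.nanmax(cube[ctrl_idx], axis=0)
    full_counts = (cube[case_idx] > full_ctrl_max).sum(axis=0)

    candidates = []
    for i, j in zip(*np.nonzero(hits)):
        freq = hits[i, j] / reps
        if freq < max(min_frequency, np.finfo(float).tiny):
            continue
        candidates.append(RatioCandidate(
            ratio=GeneRatio(expr.probe_ids[i], expr.probe_ids[j]),
            separation_count=int(full_counts[i, j]),
            selection_frequency=float(freq),
        ))
    candidates.sort(key=lambda c: (-c.selection_frequency, -c.separation_count,
                                   c.ratio.numerator_probe, c.ratio.denominator_probe))
    return candidates


def _coverage_sets(candidates: Sequence[RatioCandidate], expr: ExpressionMatrix,
                   case_idx: np.ndarray, ctrl_idx: np.ndarray
                   ) -> tuple[list[frozenset[int]], list[float]]:
    covered: list[frozenset[int]] = []
    thresholds: list[float] = []
    for cand in candidates:
        vals = ratio_values(expr, cand.ratio)
        ctrl_vals = vals[ctrl_idx]
        ctrl_vals = ctrl_vals[np.isfinite(ctrl_vals)]
        if ctrl_vals.size == 0:
            covered.append(frozenset())
            thresholds.append(math.inf)
            continue
        thr = float(ctrl_vals.max())
        case_vals = vals[case_idx]
        covered.append(frozenset(np.where(case_vals > thr)[0].tolist()))
        thresholds.append(thr)
    return covered, thresholds


def greedy_cover(sets: Sequence[frozenset[int]]) -> list[int]:
    """Greedy maximum-coverage: indices of sets chosen until marginal gain is 0.

    Ties are broken by position in ``sets`` (callers pass candidates in rank
    order, so earlier-ranked candidates win ties).
    """
    chosen: list[int] = []
    covered: set[int] = set()
    remaining = list(range(len(sets)))
    while True:
        best, best_gain = None, 0
        for idx in remaining:
            gain = len(sets[idx] - covered)
            if gain > best_gain:
                best, best_gain = idx, gain
        if best is None:
            return chosen
        chosen.append(best)
        covered |= sets[best]
        remaining.remove(best)


def select_panel(candidates: Sequence[RatioCandidate], expr: ExpressionMatrix,
                 case_label: str, control_label: str) -> RatioPanel:
    """Greedy forward selection of the covering ratio panel on full training data.

    A case subject is covered by a ratio when its value strictly exceeds the
    training-control maximum.  Ratios are added in order of marginal coverage
    gain (ties by candidate rank) and growth stops at the first zero gain;
    thresholds are the full-training-control maxima.
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    case_idx = _group_indices(expr, case_label)
    ctrl_idx = _group_indices(expr, control_label)
    covered, thresholds = _coverage_sets(candidates, expr, case_idx, ctrl_idx)
    chosen = greedy_cover(covered)
    if not chosen:
        logger.warning("no candidate covers any case subject; returning empty panel")
    return RatioPanel(
        ratios=[candidates[i].ratio for i in chosen],
        thresholds=[thresholds[i] for i in chosen],
        case_label=case_label,
        control_label=control_label,
    )


def score_subjects(panel: RatioPanel, expr: ExpressionMatrix,
                   subject_ids: Sequence[str] | None = None) -> list[ScoreResult]:
    """Score subjects against a panel: indicator_i = 1 iff ratio_i > threshold_i.

    The ratioscore is the number of 1s; the call is positive iff it is >= 1.
    Subjects with a missing level on a panel probe get indicator 0 for the
    affected ratios (the exceedance cannot be demonstrated).
    """
    for ratio in panel.ratios:
        for probe in (ratio.numerator_probe, ratio.denominator_probe):
            if probe not in expr.probe_ids:
                raise KeyError(
                    f"panel probe {probe!r} (ratio {ratio.name}) missing from data"
                )
    subjects = list(subject_ids) if subject_ids is not None else list(expr.subject_ids)
    rows = np.array([expr.subject_index(s) for s in subjects], dtype=int)
    values = np.column_stack([ratio_values(expr, r)[rows] for r in panel.ratios]) \
        if panel.ratios else np.zeros((len(subjects), 0))
    thr = np.asarray(panel.thresholds)
    with np.errstate(invalid="ignore"):
        indicators = (values > thr).astype(int)
    results = []
    for row, subject in enumerate(subjects):
        tup = tuple(int(v) for v in indicators[row])
        score = int(sum(tup))
        results.append(ScoreResult(
            subject_id=subject, indicator_tuple=tup, ratioscore=score,
            call="positive" if score >= 1 else "negative",
        ))
    return results


def coverage(results: Iterable[ScoreResult]) -> float:
    """Fraction of subjects with ratioscore >= 1."""
    results = list(results)
    if not results:
        raise ValueError("no score results supplied")
    return sum(r.ratioscore >= 1 for r in results) / len(results)


def permute_labels(groups: dict[str, str], seed: int) -> dict[str, str]:
    """Label-permutation null utility: shuffle group labels across subjects."""
    rng = np.random.default_rng(seed)
    subjects = list(groups)
    labels = [groups[s] for s in subjects]
    rng.shuffle(labels)
    return dict(zip(subjects, labels))


def scores_frame(results: Sequence[ScoreResult]) -> pd.DataFrame:
    """TSV-ready frame: subject_id, indicator tuple, score, call."""
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in results],
        "indicator_tuple": ["".join(map(str, r.indicator_tuple)) for r in results],
        "ratioscore": [r.ratioscore for r in results],
        "call": [r.call for r in results],
    })
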
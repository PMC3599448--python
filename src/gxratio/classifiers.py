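"""Kernel classifiers trained on the same two-gene ratio features as the scoring panel.

Two training protocols are provided:

* ``subset_grid`` — repeated random 60% training subsets; for every subset and
  every (kernel parameter, soft-margin C) grid point a soft-margin kernel
  classifier is fitted and judged by its error count on the *full* data set;
  the fit with the fewest total errors wins.
* ``cv_holdout`` — a single stratified holdout split (50/60/80% training);
  kernel parameters tuned by stratified L-fold cross-validation inside the
  training portion, final fit on the whole training portion, accuracy
  reported separately for the total, training and validation sets.

Features are log2 ratio values, standardised on whatever data the classifier
was fitted to (kernel machines are scale-sensitive).  A fitted model stores
its support vectors and dual coefficients explicitly, so decisions are
reproducible after JSON round-trips without any fitted library object.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import accuracy_blocks
from .expression_io import ExpressionMatrix, merge_labels
from .ratioscore import (GeneRatio, RatioPanel, ratio_values, search_candidates,
                         select_panel)

logger = logging.getLogger(__name__)

RBF = "radial_basis"
POLY = "polynomial"


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus its parameters: width β (radial basis) or integer
    degree (polynomial), and the soft-margin cost C."""

    family: str
    width_or_degree: float
    soft_margin_C: float

    def __post_init__(self) -> None:
        if self.family not in (RBF, POLY):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.width_or_degree <= 0 or self.soft_margin_C <= 0:
            raise ValueError("kernel parameters must be positive")
        if self.family == POLY and int(self.width_or_degree) != self.width_or_degree:
            raise ValueError("polynomial degree must be an integer >= 1")


def default_grid(kernel_family: str = RBF) -> list[tuple[float, float]]:
    """(width-or-degree, C) grid: 2^-6..2^6 for β and C; degrees 1..4 for poly."""
    cs = [2.0 ** e for e in range(-6, 7)]
    if kernel_family == RBF:
        widths = [2.0 ** e for e in range(-6, 7)]
    else:
        widths = [1.0, 2.0, 3.0, 4.0]
    return [(w, c) for w in widths for c in cs]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    protocol: str  # "subset_grid" or "cv_holdout"
    seed: int
    train_fraction: float = 0.6
    n_folds: int = 10
    n_random_subsets: int = 50
    kernel_family: str = RBF
    grid: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("subset_grid", "cv_holdout"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.seed is None:
            raise ValueError("seed is required")

    def resolved_grid(self) -> list[tuple[float, float]]:
        grid = (default_grid(self.kernel_family) if self.grid is None
                else list(self.grid))
        if not grid:
            raise ValueError("parameter grid is empty")
        return grid


def build_features(expr: ExpressionMatrix, panel: RatioPanel | Sequence[GeneRatio]
                   ) -> np.ndarray:
    """Subjects x ratios matrix of log2 ratio values, in panel order."""
    ratios = panel.ratios if isinstance(panel, RatioPanel) else list(panel)
    if not ratios:
        raise ValueError("panel is empty")
    cols = [ratio_values(expr, r) for r in ratios]
    X = np.log2(np.column_stack(cols))
    if not np.all(np.isfinite(X)):
        bad = [ratios[j].name for j in range(X.shape[1])
               if not np.all(np.isfinite(X[:, j]))]
        raise ValueError(f"non-finite feature values for ratios {bad}")
    return X


@dataclasses.dataclass
class FittedClassifier:
    """A fitted binary soft-margin kernel classifier over ratio features.

    ``classes`` is sorted; the decision score is positive for ``classes[1]``.
    """

    kernel: KernelSpec
    classes: tuple[str, str]
    feature_ratios: list[GeneRatio] | None
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    training_subject_ids: list[str] = dataclasses.field(default_factory=list)

    def _kernel_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.kernel.family == RBF:
            sq = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-self.kernel.width_or_degree * sq)
        return (1.0 + X @ self.support_vectors.T) ** int(self.kernel.width_or_degree)

    def decision_scores(self, features: np.ndarray) -> np.ndarray:
        X = (np.asarray(features, dtype=float) - self.scaler_mean) / self.scaler_scale
        return self._kernel_matrix(X) @ self.dual_coef + self.intercept

    def decision_scores_for(self, label: str, features: np.ndarray) -> np.ndarray:
        """Decision scores oriented so larger means more ``label``-like."""
        if label not in self.classes:
            raise ValueError(f"label {label!r} not among classes {self.classes}")
        scores = self.decision_scores(features)
        return scores if label == self.classes[1] else -scores

    def predict(self, features: np.ndarray) -> list[str]:
        scores = self.decision_scores(features)
        return [self.classes[1] if s > 0 else self.classes[0] for s in scores]

    def _features_from(self, expr: ExpressionMatrix) -> np.ndarray:
        if self.feature_ratios is None:
            raise ValueError("classifier carries no feature panel")
        return build_features(expr, self.feature_ratios)

    def predict_expr(self, expr: ExpressionMatrix) -> list[str]:
        return self.predict(self._features_from(expr))

    def decision_scores_expr(self, expr: ExpressionMatrix) -> np.ndarray:
        return self.decision_scores(self._features_from(expr))

    def to_json(self) -> str:
        return json.dumps({
            "kernel": dataclasses.asdict(self.kernel),
            "classes": list(self.classes),
            "feature_ratios": None if self.feature_ratios is None else [
                {"numerator": r.numerator_probe, "denominator": r.denominator_probe}
                for r in self.feature_ratios
            ],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "training_subject_ids": self.training_subject_ids,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FittedClassifier":
        d = json.loads(text)
        ratios = d["feature_ratios"]
        return cls(
            kernel=KernelSpec(**d["kernel"]),
            classes=tuple(d["classes"]),
            feature_ratios=None if ratios is None else [
                GeneRatio(r["numerator"], r["denominator"]) for r in ratios
            ],
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            support_vectors=np.array(d["support_vectors"]),
            dual_coef=np.array(d["dual_coef"]),
            intercept=float(d["intercept"]),
            training_subject_ids=list(d["training_subject_ids"]),
        )


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def _fit_kernel_classifier(X: np.ndarray, y: Sequence[str], spec: KernelSpec,
                           feature_ratios: Sequence[GeneRatio] | None = None,
                           training_subject_ids: Sequence[str] | None = None
                           ) -> FittedClassifier:
    """Fit one soft-margin kernel classifier (standardising on X)."""
    classes = tuple(sorted(set(y)))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    mean, scale = _standardize_params(X)
    Xs = (X - mean) / scale
    if spec.family == RBF:
        svc = SVC(kernel="rbf", gamma=spec.width_or_degree, C=spec.soft_margin_C)
    else:
        svc = SVC(kernel="poly", degree=int(spec.width_or_degree), gamma=1.0,
                  coef0=1.0, C=spec.soft_margin_C)
    svc.fit(Xs, list(y))
    return FittedClassifier(
        kernel=spec,
        classes=classes,
        feature_ratios=list(feature_ratios) if feature_ratios is not None else None,
        scaler_mean=mean,
        scaler_scale=scale,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        training_subject_ids=list(training_subject_ids or []),
    )


def _stratified_subset(rng: np.random.Generator, labels: np.ndarray,
                       fraction: float) -> np.ndarray:
    """Indices of a stratified random subset with >= 1 subject per class."""
    chosen: list[np.ndarray] = []
    for label in sorted(set(labels)):
        idx = np.where(labels == label)[0]
        k = max(1, int(round(fraction * idx.size)))
        chosen.append(rng.choice(idx, size=k, replace=False))
    return np.sort(np.concatenate(chosen))


def train_subset_grid(features: np.ndarray, labels: Sequence[str],
                      config: TrainConfig,
                      feature_ratios: Sequence[GeneRatio] | None = None,
                      subject_ids: Sequence[str] | None = None) -> FittedClassifier:
    """Protocol #1: random training subsets x parameter grid, judged on full data.

    Returns the fitted classifier (fit on its winning subset) at the
    (subset, grid point) combination with the fewest misclassifications over
    the full data set; ties go to the earliest combination, so the result is
    deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(list(labels))
    if len(set(y)) != 2:
        raise ValueError("subset_grid protocol requires binary labels")
    grid = config.resolved_grid()
    rng = np.random.default_rng(config.seed)
    subject_ids = list(subject_ids) if subject_ids is not None else []

    best: tuple[int, FittedClassifier] | None = None
    for _ in range(config.n_random_subsets):
        sub = _stratified_subset(rng, y, config.train_fraction)
        for width, cost in grid:
            spec = KernelSpec(config.kernel_family, width, cost)
            clf = _fit_kernel_classifier(
                X[sub], y[sub], spec, feature_ratios,
                [subject_ids[i] for i in sub] if subject_ids else None)
            errors = int(np.sum(np.asarray(clf.predict(X)) != y))
            if best is None or errors < best[0]:
                best = (errors, clf)
    assert best is not None
    logger.info("subset_grid: best fit has %d/%d errors on the full set",
                best[0], len(y))
    return best[1]


def _cv_accuracy(X: np.ndarray, y: np.ndarray, spec: KernelSpec,
                 n_folds: int, seed: int) -> float:
    """Mean stratified K-fold accuracy; folds shrink if a class is too small."""
    class_min = min(np.sum(y == c) for c in set(y))
    folds = max(2, min(n_folds, int(class_min)))
    if folds < n_folds:
        logger.warning("re-stratifying: reducing folds from %d to %d", n_folds, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(X, y):
        clf = _fit_kernel_classifier(X[train], y[train], spec)
        accs.append(float(np.mean(np.asarray(clf.predict(X[test])) == y[test])))
    return float(np.mean(accs))


def train_cv_holdout(features: np.ndarray, labels: Sequence[str],
                     config: TrainConfig,
                     feature_ratios: Sequence[GeneRatio] | None = None,
                     subject_ids: Sequence[str] | None = None
                     ) -> tuple[FittedClassifier, dict[str, dict[str, int]]]:
    """Protocol #2: holdout split + L-fold CV tuning inside the training portion.

    Returns the final classifier (fit on the whole training portion at the
    CV-best grid point) and Tc/Ti/TOTAL/%I accuracy blocks for the total,
    training and validation sets.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(list(labels))
    if len(set(y)) != 2:
        raise ValueError("cv_holdout protocol requires binary labels")
    grid = config.resolved_grid()
    rng = np.random.default_rng(config.seed)
    train_idx = _stratified_subset(rng, y, config.train_fraction)
    valid_idx = np.setdiff1d(np.arange(len(y)), train_idx)

    best_spec, best_acc = None, -1.0
    for width, cost in grid:
        spec = KernelSpec(config.kernel_family, width, cost)
        acc = _cv_accuracy(X[train_idx], y[train_idx], spec,
                           config.n_folds, config.seed)
        if acc > best_acc:
            best_spec, best_acc = spec, acc
    assert best_spec is not None

    subject_ids = list(subject_ids) if subject_ids is not None else []
    clf = _fit_kernel_classifier(
        X[train_idx], y[train_idx], best_spec, feature_ratios,
        [subject_ids[i] for i in train_idx] if subject_ids else None)

    def block(idx: np.ndarray) -> dict[str, int]:
        pred = np.asarray(clf.predict(X[idx]))
        correct = int(np.sum(pred == y[idx]))
        return accuracy_blocks(correct, len(idx) - correct)

    blocks = {
        "total": block(np.arange(len(y))),
        "training": block(train_idx),
        "validation": block(valid_idx),
    }
    return clf, blocks


# ---------------------------------------------------------------------------
# Multiclass (pairwise voting) and the tiered two-stage scheme

@dataclasses.dataclass
class PairwiseVotingClassifier:
    """One-vs-one voting over binary kernel classifiers on shared ratio features.

    Ties are broken by summed signed decision scores, then alphabetically.
    """

    classes: tuple[str, ...]
    feature_ratios: list[GeneRatio]
    pairwise: dict[tuple[str, str], FittedClassifier]

    def predict_expr(self, expr: ExpressionMatrix) -> list[str]:
        X = build_features(expr, self.feature_ratios)
        votes = {c: np.zeros(len(X)) for c in self.classes}
        margins = {c: np.zeros(len(X)) for c in self.classes}
        for (a, b), clf in self.pairwise.items():
            scores = clf.decision_scores(X)
            lo, hi = clf.classes  # score > 0 -> hi
            for s in range(len(X)):
                winner = hi if scores[s] > 0 else lo
                votes[winner][s] += 1
            margins[hi] += scores
            margins[lo] -= scores
        out = []
        for s in range(len(X)):
            ranked = sorted(self.classes,
                            key=lambda c: (-votes[c][s], -margins[c][s], c))
            out.append(ranked[0])
        return out


def train_multiclass(expr: ExpressionMatrix, ratio_set_mode: str,
                     class_labels: Sequence[str] = ("CTRL", "UC", "CD"),
                     control_label: str = "CTRL",
                     seed: int = 0, reps: int = 50, top_k: int = 100,
                     max_candidates: int = 100,
                     kernel: KernelSpec | None = None) -> PairwiseVotingClassifier:
    """Three-class classifier by pairwise voting on a shared ratio feature set.

    ``ratio_set_mode='case_vs_control'`` takes the panel from a single search
    of controls against the pooled non-control classes; ``'union'``
    concatenates the three pairwise panels (deduplicated), which gives each
    pairwise distinction its own discriminative ratios.
    """
    class_labels = tuple(class_labels)
    present = {g for g in expr.groups.values()}
    missing = [c for c in class_labels if c not in present]
    if len(class_labels) != 3 or missing:
        raise ValueError(
            f"need exactly the three classes {class_labels}; missing {missing}"
        )
    if ratio_set_mode not in ("case_vs_control", "union"):
        raise ValueError(f"unknown ratio_set_mode {ratio_set_mode!r}")
    cases = [c for c in class_labels if c != control_label]

    keep = [s for s in expr.subject_ids if expr.groups[s] in class_labels]
    data = expr.subset(keep)

    def pairwise_panel(sub: ExpressionMatrix, case: str, control: str,
                       search_seed: int) -> list[GeneRatio]:
        cands = search_candidates(sub, case, control, reps=reps, top_k=top_k,
                                  seed=search_seed)[:max_candidates]
        return select_panel(cands, sub, case, control).ratios

    if ratio_set_mode == "case_vs_control":
        pooled = merge_labels(data, {c: cases[0] for c in cases})
        ratios = pairwise_panel(pooled, cases[0], control_label, seed)
    else:
        ratios = []
        seen = set()
        searches = [(cases[0], control_label), (cases[1], control_label),
                    (cases[0], cases[1])]
        for offset, (case, control) in enumerate(searches):
            pair_subjects = [s for s in data.subject_ids
                             if data.groups[s] in (case, control)]
            sub = data.subset(pair_subjects)
            for ratio in pairwise_panel(sub, case, control, seed + offset):
                if ratio not in seen:
                    seen.add(ratio)
                    ratios.append(ratio)
    if not ratios:
        raise ValueError("ratio search produced no covering panel")

    kernel = kernel or KernelSpec(RBF, 1.0 / len(ratios), 10.0)
    X = build_features(data, ratios)
    y = np.asarray([data.groups[s] for s in data.subject_ids])
    pairwise: dict[tuple[str, str], FittedClassifier] = {}
    labels_sorted = tuple(sorted(class_labels))
    for i, a in enumerate(labels_sorted):
        for b in labels_sorted[i + 1:]:
            mask = (y == a) | (y == b)
            pairwise[(a, b)] = _fit_kernel_classifier(
                X[mask], y[mask], kernel, ratios,
                [s for s, m in zip(data.subject_ids, mask) if m])
    return PairwiseVotingClassifier(classes=labels_sorted,
                                    feature_ratios=list(ratios),
                                    pairwise=pairwise)


def tiered_classify(expr: ExpressionMatrix, stage1_model: FittedClassifier,
                    stage2_model: FittedClassifier,
                    stage1_positive: str = "IBD") -> dict[str, str]:
    """Two-stage routing: stage 1 splits IBD from IBS; IBD-positives go to
    stage 2 (CD vs UC); IBS-assigned subjects never receive a stage-2 label."""
    stage1 = stage1_model.predict_expr(expr)
    stage2 = stage2_model.predict_expr(expr)
    out: dict[str, str] = {}
    for subject, s1, s2 in zip(expr.subject_ids, stage1, stage2):
        out[subject] = s2 if s1 == stage1_positive else s1
    return out
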
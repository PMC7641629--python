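"""Nested cross-validated RBF-SVM classification of edge features.

Outer stratified 10-fold cross-validation estimates generalisation; inside
every outer training fold, mRMR ranks the edges and the drop rule fixes
how many to keep, then an inner stratified k-fold grid search tunes the
soft-margin parameter C and the Gaussian kernel scale s (the kernel is
k(x, y) = exp(-||x - y||^2 / (2 s^2)), i.e. gamma = 1 / (2 s^2)).  Edge
features are z-scored with training-fold statistics before the kernel is
applied.  Nothing derived from a test fold ever enters selection, scaling
or tuning; tests assert this by mutating test-fold data.

The whole nested procedure is repeated over many random outer partitions;
the "optimal" repetition (highest mean test accuracy, ties broken by AUC
then seed order) is the one whose fold-wise selections define the
consensus "major features".  The positive class is the patient group
throughout, so sensitivity is the patient detection rate.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectome import RegionAtlas, edge_annotation
from .mrmr import DiscretizationRule, bottom_rank_features, miq_rank

SelectorFn = Callable[[np.ndarray, np.ndarray, int], np.ndarray]


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameter search space for the RBF-SVM inner loop.

    ``c_grid`` defaults to the logarithmic grid 2^-5 .. 2^15 in powers of
    four; kernel scales are ``scale_factors * sqrt(n_features)``.
    """

    c_grid: tuple[float, ...] = tuple(float(2.0 ** k) for k in range(-5, 16, 2))
    scale_factors: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    inner_folds: int = 10

    def __post_init__(self) -> None:
        if not self.c_grid or not self.scale_factors:
            raise ValueError("hyperparameter grids must be nonempty")
        if min(self.c_grid) <= 0 or min(self.scale_factors) <= 0:
            raise ValueError("hyperparameter grids must be positive")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")

    @classmethod
    def compact(cls) -> "SVMConfig":
        """Coarser grid for desk-scale cohorts (same coverage in log-space,
        far fewer fits)."""
        return cls(c_grid=tuple(float(2.0 ** k) for k in (-3, 1, 5, 9, 13)),
                   scale_factors=(0.5, 1.0, 2.0), inner_folds=5)


@dataclass
class FoldPlan:
    """Outer-fold assignment: ``assignment[i]`` is the fold id of subject i."""

    n_folds: int
    assignment: np.ndarray
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class FoldResult:
    fold: int
    test_indices: np.ndarray
    selected: np.ndarray
    k_selected: int
    c: float
    scale: float
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    metrics: dict


@dataclass
class CVResult:
    """One full nested-CV repetition: per-fold details plus fold-averaged
    metrics (mean and sd of accuracy, sensitivity, specificity, AUC)."""

    seed: int
    folds: list[FoldResult]
    predictions: np.ndarray
    scores: np.ndarray
    summary: dict

    @property
    def mean_accuracy(self) -> float:
        return self.summary["accuracy_mean"]

    @property
    def mean_auc(self) -> float:
        return self.summary["auc_mean"]

    def mean_k_selected(self) -> float:
        return float(np.mean([f.k_selected for f in self.folds]))


@dataclass
class RepeatedCVResult:
    repetitions: list[CVResult]
    optimal_index: int
    summary: pd.DataFrame  # one row per repetition

    @property
    def optimal(self) -> CVResult:
        return self.repetitions[self.optimal_index]

    def aggregate(self) -> dict:
        """Mean +/- sd of each metric across repetitions."""
        out = {}
        for m in ("accuracy", "sensitivity", "specificity", "auc"):
            vals = self.summary[f"{m}_mean"].to_numpy()
            out[f"{m}_mean"] = float(np.mean(vals))
            out[f"{m}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return out


def make_folds(labels: Sequence[int], n_folds: int = 10, seed: int = 0,
               stratified: bool = True) -> FoldPlan:
    """Partition subjects into outer folds (stratified by default, so fold
    sizes differ by at most one within each class)."""
    y = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < n_folds:
            raise ValueError(
                f"stratified folding impossible: smallest class has "
                f"{counts.min()} members for {n_folds} folds")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for f, (_, test) in enumerate(splitter.split(np.zeros(len(y)), y)):
        assignment[test] = f
    return FoldPlan(n_folds=n_folds, assignment=assignment, seed=seed,
                    stratified=stratified)


def tune_svm(x: np.ndarray, y: np.ndarray, config: SVMConfig = SVMConfig(),
             seed: int = 0) -> tuple[float, float, float]:
    """Inner-CV grid search; returns (C, kernel scale, best inner accuracy).

    Ties break to the smallest C, then the smallest scale (the grids are
    scanned in ascending order and only strict improvements replace the
    incumbent).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for tuning")
    p = x.shape[1]
    splitter = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                               random_state=seed)
    folds = []
    for tr, te in splitter.split(x, y):
        scaler = StandardScaler().fit(x[tr])
        folds.append((scaler.transform(x[tr]), y[tr],
                      scaler.transform(x[te]), y[te]))
    base_scale = math.sqrt(p)
    best = (-1.0, None, None)
    for c in sorted(config.c_grid):
        for factor in sorted(config.scale_factors):
            scale = factor * base_scale
            gamma = 1.0 / (2.0 * scale * scale)
            acc = 0.0
            for xtr, ytr, xte, yte in folds:
                model = SVC(C=c, kernel="rbf", gamma=gamma)
                model.fit(xtr, ytr)
                acc += float(np.mean(model.predict(xte) == yte))
            acc /= len(folds)
            if acc > best[0]:
                best = (acc, c, scale)
    return best[1], best[2], best[0]


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           scores: Optional[np.ndarray] = None,
                           positive: int = 1) -> dict:
    """Accuracy, sensitivity (patient recall), specificity (control
    recall) and tie-averaged AUC of the decision scores.

    AUC equals the normalised Mann-Whitney statistic (ties count 1/2); it
    is NaN, with ``auc_defined`` False, when only one class is present.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    neg = ~pos
    tp = int(np.sum(pos & (y_pred == positive)))
    tn = int(np.sum(neg & (y_pred != positive)))
    n = y_true.size
    acc = (tp + tn) / n
    sens = tp / pos.sum() if pos.sum() else math.nan
    spec = tn / neg.sum() if neg.sum() else math.nan
    auc = math.nan
    auc_defined = False
    if scores is not None and pos.sum() and neg.sum():
        if not np.all(np.isfinite(scores)):
            raise ValueError("decision scores must be finite")
        auc = float(roc_auc_score((y_true == positive).astype(int), scores))
        auc_defined = True
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "auc": auc, "auc_defined": auc_defined}


def _mrmr_selector(rule: DiscretizationRule, max_k: int, redundancy: str,
                   drop_ratio: Optional[float]) -> SelectorFn:
    def select(xtr: np.ndarray, ytr: np.ndarray, _seed: int) -> np.ndarray:
        ranking = miq_rank(xtr, ytr, max_k=max_k, rule=rule,
                           redundancy=redundancy, drop_ratio=drop_ratio)
        return ranking.selected
    return select


def run_nested_cv(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    svm_config: SVMConfig = SVMConfig(),
    mrmr_rule: DiscretizationRule = DiscretizationRule(),
    n_outer: int = 10,
    max_k: int = 50,
    redundancy: str = "mean",
    drop_ratio: Optional[float] = None,
    selector: Optional[SelectorFn] = None,
) -> CVResult:
    """One nested-CV repetition on the (subjects x edges) feature table.

    ``selector(x_train, y_train, fold_seed) -> edge indices`` defaults to
    the in-fold mRMR ranking with the drop cutoff; control experiments
    pass a different selector through the same machinery.  Each subject is
    predicted exactly once.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if selector is None:
        selector = _mrmr_selector(mrmr_rule, max_k, redundancy, drop_ratio)
    plan = make_folds(y, n_folds=n_outer, seed=seed, stratified=True)
    predictions = np.full(y.size, -1, dtype=int)
    decision = np.full(y.size, np.nan, dtype=float)
    fold_results: list[FoldResult] = []
    for f in range(n_outer):
        tr = plan.train_indices(f)
        te = plan.test_indices(f)
        fold_seed = int((seed * 1009 + 7919 * f + 1) % (2 ** 31))
        feats = np.asarray(selector(x[tr], y[tr], fold_seed), dtype=int)
        if feats.size == 0:
            raise ValueError(f"selector returned no features in fold {f}")
        c, scale, _ = tune_svm(x[np.ix_(tr, feats)], y[tr], svm_config,
                               seed=fold_seed)
        scaler = StandardScaler().fit(x[np.ix_(tr, feats)])
        model = SVC(C=c, kernel="rbf", gamma=1.0 / (2.0 * scale * scale))
        model.fit(scaler.transform(x[np.ix_(tr, feats)]), y[tr])
        xte = scaler.transform(x[np.ix_(te, feats)])
        y_pred = model.predict(xte)
        scores = model.decision_function(xte)
        predictions[te] = y_pred
        decision[te] = scores
        fold_results.append(FoldResult(
            fold=f, test_indices=te, selected=feats, k_selected=feats.size,
            c=c, scale=scale, y_true=y[te], y_pred=y_pred, scores=scores,
            metrics=classification_metrics(y[te], y_pred, scores),
        ))
    if np.any(predictions < 0):
        raise RuntimeError("internal error: some subjects were never predicted")
    summary = _summarise_folds(fold_results)
    return CVResult(seed=seed, folds=fold_results, predictions=predictions,
                    scores=decision, summary=summary)


def _summarise_folds(folds: list[FoldResult]) -> dict:
    out = {}
    for m in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = np.array([f.metrics[m] for f in folds], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[f"{m}_mean"] = float(vals.mean()) if vals.size else math.nan
        out[f"{m}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return out


def repeat_partitions(
    x: np.ndarray,
    y: np.ndarray,
    n_repetitions: int = 100,
    base_seed: int = 0,
    **cv_kwargs,
) -> RepeatedCVResult:
    """Run the nested CV over ``n_repetitions`` random outer partitions.

    The optimal repetition has the highest mean test accuracy; ties go to
    the higher mean AUC, then the earlier repetition.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    seeds = [int((base_seed + 104729 * i) % (2 ** 31)) for i in range(n_repetitions)]
    reps = [run_nested_cv(x, y, seed=s, **cv_kwargs) for s in seeds]
    rows = []
    for i, r in enumerate(reps):
        row = {"repetition": i, "seed": r.seed}
        row.update(r.summary)
        rows.append(row)
    summary = pd.DataFrame(rows)
    best = max(range(len(reps)),
               key=lambda i: (reps[i].mean_accuracy,
                              reps[i].mean_auc if math.isfinite(reps[i].mean_auc) else -1.0,
                              -i))
    return RepeatedCVResult(repetitions=reps, optimal_index=best, summary=summary)


def major_features(
    cv: CVResult,
    x: np.ndarray,
    y: np.ndarray,
    atlas: Optional[RegionAtlas] = None,
    min_count: int = 9,
) -> pd.DataFrame:
    """Consensus edges selected in at least ``min_count`` of the outer
    folds, annotated with region/network labels (when an atlas is given)
    and the sign of the patient-minus-control mean Fisher-z difference."""
    if min_count > len(cv.folds):
        return pd.DataFrame(columns=["edge", "count", "patient_minus_control",
                                     "patients_higher"])
    counts = Counter()
    for f in cv.folds:
        counts.update(int(k) for k in f.selected)
    y = np.asarray(y, dtype=int)
    rows = []
    for k, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        if c < min_count:
            continue
        diff = float(x[y == 1, k].mean() - x[y == 0, k].mean())
        row = {"edge": k, "count": c, "patient_minus_control": diff,
               "patients_higher": diff > 0}
        if atlas is not None:
            row.update(edge_annotation(k, atlas))
        rows.append(row)
    return pd.DataFrame(rows)


def control_experiment(
    x: np.ndarray,
    y: np.ndarray,
    mode: str,
    n_features: int,
    seed: int = 0,
    svm_config: SVMConfig = SVMConfig(),
    mrmr_rule: DiscretizationRule = DiscretizationRule(),
    n_outer: int = 10,
) -> CVResult:
    """Run the identical CV machinery with a control feature set.

    ``low_score``: per-training-fold, the ``n_features`` lowest-relevance
    edges (the negative control mirroring the low-importance comparison).
    ``random``: one global random subset of size ``n_features`` drawn from
    ``seed`` and reused in every fold.
    """
    x = np.asarray(x, dtype=float)
    e = x.shape[1]
    if n_features > e:
        raise ValueError("n_features exceeds the number of edges")
    if mode == "low_score":
        if n_features == e:
            selector: SelectorFn = lambda xtr, ytr, s: np.arange(e)
        else:
            selector = lambda xtr, ytr, s: bottom_rank_features(
                xtr, ytr, n_features, mrmr_rule)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        subset = np.sort(rng.choice(e, size=n_features, replace=False))
        selector = lambda xtr, ytr, s: subset
    else:
        raise ValueError("mode must be 'low_score' or 'random'")
    return run_nested_cv(x, y, seed=seed, svm_config=svm_config,
                         n_outer=n_outer, selector=selector)
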
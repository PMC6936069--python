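"""Leave-one-out classifier evaluation with explicit ROC/AUC conventions.

Classifier internals are delegated to scikit-learn; the evaluation
mathematics is bespoke and follows the conventions of the study design this
package targets:

* every subject is scored by a model trained on all other subjects (LOOCV),
  features z-scored within each training fold only;
* SVM-family classifiers emit the signed margin and are swept over the range
  of observed scores ("score_range" thresholds); probabilistic classifiers
  emit the class-1 probability and are swept over an even grid on [0, 1]
  ("unit_interval" thresholds);
* at threshold t a subject is predicted positive iff score >= t;
  TPR = TP/P and FPR = FP/N; AUC is the trapezoidal integral of TPR over FPR.

Two bespoke feature-selection wrappers are provided: recursive feature
elimination with a linear SVM ranking, and binary particle swarm
optimization with an internal cross-validated AUC fitness.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix, extract_features

__all__ = [
    "ClassifierSpec",
    "RocResult",
    "CLASSIFIER_KINDS",
    "SVM_KINDS",
    "loocv_scores",
    "roc_curve",
    "auc",
    "rfe_select",
    "pso_select",
    "evaluate_classifier",
    "compare_feature_scopes",
]

CLASSIFIER_KINDS = (
    "linear_svm",
    "pso_svm",
    "rfe_svm",
    "random_forest",
    "lda",
    "lasso_logistic",
    "knn",
)

#: Kinds scored by the signed margin and swept over the score range.
SVM_KINDS = ("linear_svm", "pso_svm", "rfe_svm")


@dataclasses.dataclass
class ClassifierSpec:
    """A classifier kind plus hyperparameters and the seed controlling it."""

    kind: str
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; choose from {CLASSIFIER_KINDS}")

    @property
    def threshold_mode(self) -> str:
        return "score_range" if self.kind in SVM_KINDS else "unit_interval"


@dataclasses.dataclass
class RocResult:
    """A threshold sweep: TPR/FPR per threshold plus the trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def _base_estimator(spec: ClassifierSpec, seed):
    hp = spec.hyperparameters
    if spec.kind in SVM_KINDS:
        return SVC(kernel="linear", C=hp.get("C", 1.0))
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.get("n_estimators", 500), random_state=seed
        )
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    if spec.kind == "lasso_logistic":
        return LogisticRegression(
            solver="liblinear", l1_ratio=1.0, C=hp.get("C", 1.0), random_state=seed
        )
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 5))
    raise AssertionError(spec.kind)


def _scores_from(clf, X, svm_family: bool) -> np.ndarray:
    if svm_family:
        return np.asarray(clf.decision_function(X), dtype=float)
    return np.asarray(clf.predict_proba(X)[:, 1], dtype=float)


def _coerce_Xy(fm_or_X, y):
    if isinstance(fm_or_X, FeatureMatrix):
        if y is None:
            y = fm_or_X.labels
        return fm_or_X.features, np.asarray(y)
    return np.asarray(fm_or_X, dtype=float), np.asarray(y)


def loocv_scores(fm: FeatureMatrix, spec: ClassifierSpec) -> np.ndarray:
    """Leave-one-out decision scores, one per subject.

    Feature selection for the pso_svm / rfe_svm kinds is re-run inside every
    training fold, so the held-out subject never informs the selection.
    """
    X, y = _coerce_Xy(fm, None)
    if y is None:
        raise ValueError("feature matrix has no labels")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must be binary")
    if np.bincount((y == classes.max()).astype(int)).min() < 2:
        raise ValueError("need at least 2 subjects per class for LOOCV")

    n = X.shape[0]
    fold_seeds = np.random.SeedSequence(spec.seed).generate_state(n)
    scores = np.empty(n)
    svm_family = spec.kind in SVM_KINDS
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        Xtr, ytr = X[train], y[train]
        cols = slice(None)
        seed_i = int(fold_seeds[i])
        if spec.kind == "rfe_svm":
            hp = spec.hyperparameters
            n_keep = min(hp.get("n_keep", 10), X.shape[1])
            cols = rfe_select(Xtr, ytr, n_keep=n_keep, step=hp.get("step", 0.5),
                              C=hp.get("C", 1.0))
        elif spec.kind == "pso_svm":
            hp = spec.hyperparameters
            mask = pso_select(
                Xtr,
                ytr,
                swarm_size=hp.get("swarm_size", 20),
                iterations=hp.get("iterations", 30),
                seed=seed_i,
                C=hp.get("C", 1.0),
            )
            cols = np.flatnonzero(mask)
        clf = make_pipeline(StandardScaler(), _base_estimator(spec, seed_i))
        clf.fit(Xtr[:, cols], ytr)
        scores[i] = _scores_from(clf, X[i : i + 1, cols], svm_family)[0]
    return scores


def roc_curve(scores, labels, threshold_mode: str = "score_range", n_grid: int = 101) -> RocResult:
    """Sweep classification thresholds and tabulate TPR/FPR.

    ``score_range`` sweeps the sorted unique scores; ``unit_interval`` sweeps
    an even ``n_grid``-point grid on [0, 1].  Both sweeps are bracketed by
    -inf/+inf so the curve always contains (1,1) and (0,0).  A subject is
    predicted positive iff its score >= threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == labels.max() if set(np.unique(labels)) != {0, 1} else labels == 1
    P = int(pos.sum())
    Nn = int((~pos).sum())
    if P == 0 or Nn == 0:
        raise ValueError("need at least one subject in each class")
    if threshold_mode == "score_range":
        inner = np.unique(scores)
    elif threshold_mode == "unit_interval":
        inner = np.linspace(0.0, 1.0, n_grid)
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    thresholds = np.concatenate(([-np.inf], inner, [np.inf]))
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for t_i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[t_i] = (pred & pos).sum() / P
        fpr[t_i] = (pred & ~pos).sum() / Nn
    result = RocResult(thresholds, tpr, fpr, 0.0)
    result.auc = auc(result)
    return result


def auc(roc: RocResult) -> float:
    """Trapezoidal area under TPR(FPR), sorted by (FPR, TPR)."""
    order = np.lexsort((roc.tpr, roc.fpr))
    return float(np.trapezoid(roc.tpr[order], roc.fpr[order]))


def rfe_select(fm_or_X, y=None, n_keep: int = 10, step: float = 0.5, C: float = 1.0) -> np.ndarray:
    """Recursive feature elimination with a linear-SVM |weight| ranking.

    Repeatedly trains, ranks features by absolute coefficient and drops the
    bottom ``step`` fraction (at least one) until ``n_keep`` remain.
    Returns the sorted kept feature indices.
    """
    X, y = _coerce_Xy(fm_or_X, y)
    F = X.shape[1]
    if not 1 <= n_keep <= F:
        raise ValueError(f"n_keep must be in 1..{F}")
    if not 0 < step < 1:
        raise ValueError("step must be a fraction in (0, 1)")
    remaining = np.arange(F)
    while remaining.size > n_keep:
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(X[:, remaining], y)
        w = np.abs(clf[-1].coef_.ravel())
        n_drop = min(remaining.size - n_keep, max(1, int(step * remaining.size)))
        keep = np.sort(np.argsort(w)[n_drop:])  # drop the lowest-ranked
        remaining = remaining[keep]
    return np.sort(remaining)


def _cv_auc(X, y, cols, C, seed) -> float:
    """Pooled held-out-margin AUC of a linear SVM over stratified folds."""
    n_splits = min(3, int(np.bincount(y).min()))
    if n_splits < 2:
        raise ValueError("need at least 2 subjects per class for internal CV")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    held_scores = np.empty(len(y))
    for tr, te in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(X[np.ix_(tr, cols)], y[tr])
        held_scores[te] = clf.decision_function(X[np.ix_(te, cols)])
    return roc_curve(held_scores, y, "score_range").auc


def pso_select(
    fm_or_X,
    y=None,
    swarm_size: int = 20,
    iterations: int = 30,
    seed: int | None = None,
    w_start: float = 0.9,
    w_end: float = 0.4,
    c1: float = 2.0,
    c2: float = 2.0,
    C: float = 1.0,
    full_output: bool = False,
) -> np.ndarray:
    """Binary particle swarm optimization of a feature mask.

    Each particle's position is a binary inclusion mask; fitness is the
    internal cross-validated AUC of a linear SVM on the selected columns.
    Velocities use linearly decaying inertia with cognitive/social pulls
    toward personal and global bests; positions are resampled as
    Bernoulli(sigmoid(velocity)).  The all-ones mask is seeded as one initial
    particle, so on the internal criterion the selection never ends below
    using all features.  All-zero candidate masks are repaired to one random
    feature.  Deterministic given ``seed``.  Returns the global-best mask,
    or ``(mask, info)`` with the global-best and all-ones fitness values when
    ``full_output`` is set.
    """
    X, y = _coerce_Xy(fm_or_X, y)
    if swarm_size < 2:
        raise ValueError("swarm_size must be >= 2")
    F = X.shape[1]
    y01 = (y == np.unique(y).max()).astype(int)
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31 - 1))

    def fitness(mask: np.ndarray) -> float:
        return _cv_auc(X, y01, np.flatnonzero(mask), C, cv_seed)

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(F)] = 1
        return mask

    positions = (rng.random((swarm_size, F)) < 0.5).astype(int)
    positions[0] = 1  # all-ones particle anchors the baseline
    positions = np.array([repair(p) for p in positions])
    velocities = rng.uniform(-1.0, 1.0, size=(swarm_size, F))

    pbest = positions.copy()
    pbest_fit = np.array([fitness(p) for p in positions])
    all_ones_fit = pbest_fit[0]
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    for it in range(iterations):
        inertia = w_start + (w_end - w_start) * (it / max(iterations - 1, 1))
        r1 = rng.random((swarm_size, F))
        r2 = rng.random((swarm_size, F))
        velocities = (
            inertia * velocities
            + c1 * r1 * (pbest - positions)
            + c2 * r2 * (gbest - positions)
        )
        np.clip(velocities, -6.0, 6.0, out=velocities)
        prob = 1.0 / (1.0 + np.exp(-velocities))
        positions = (rng.random((swarm_size, F)) < prob).astype(int)
        positions = np.array([repair(p) for p in positions])
        for p_i in range(swarm_size):
            fit = fitness(positions[p_i])
            if fit > pbest_fit[p_i]:
                pbest[p_i] = positions[p_i].copy()
                pbest_fit[p_i] = fit
                if fit > gbest_fit:
                    gbest, gbest_fit = positions[p_i].copy(), float(fit)
    if full_output:
        info = {"gbest_fitness": gbest_fit, "all_ones_fitness": float(all_ones_fit)}
        return gbest, info
    return gbest


def evaluate_classifier(fm: FeatureMatrix, spec: ClassifierSpec):
    """LOOCV scores plus the ROC/AUC under the kind's threshold convention."""
    scores = loocv_scores(fm, spec)
    roc = roc_curve(scores, fm.labels, spec.threshold_mode)
    return scores, roc


def compare_feature_scopes(
    nets,
    labels,
    partition,
    module_k: int,
    specs: Sequence[ClassifierSpec],
) -> pd.DataFrame:
    """LOOCV AUC of each classifier with module-scope vs whole-network features.

    Rows are the two feature scopes, columns the classifier kinds.
    """
    nets = list(nets)
    node_ids = nets[0].node_ids
    module_nodes = [node_ids[i] for i in partition.module_nodes(module_k)]
    fm_module = extract_features(nets, scope=module_nodes).with_labels(labels)
    fm_whole = extract_features(nets, scope=None).with_labels(labels)
    table = {}
    for spec in specs:
        _, roc_m = evaluate_classifier(fm_module, spec)
        _, roc_w = evaluate_classifier(fm_whole, spec)
        table[spec.kind] = {"module": roc_m.auc, "whole_network": roc_w.auc}
    return pd.DataFrame(table).reindex(["module", "whole_network"])
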
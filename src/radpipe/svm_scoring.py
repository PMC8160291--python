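"""Gaussian-kernel SVM scoring and sequential forward feature selection.

The decision value for a patient is the kernel expansion
``f(x) = sum_n w_n y_n G(x_n, x) + b`` with ``G(x_n, x) =
exp(-||x_n - x||^2)`` (unit kernel width); features are z-scored with
training-set statistics so the unit width is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


@dataclass
class SVMModel:
    """Trained kernel expansion plus the preprocessing needed to apply it."""

    support_vectors: np.ndarray      # (N, d) rows in standardized space
    weights: np.ndarray              # nonnegative dual coefficients w_n
    labels: np.ndarray               # y_n in {-1, +1}
    bias: float
    C: float
    selected_features: list[int] = field(default_factory=list)
    center: np.ndarray | None = None     # standardization mean (original space)
    scale: np.ndarray | None = None      # standardization sd

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.support_vectors) or \
                len(self.labels) != len(self.support_vectors):
            raise ValueError("one weight and one label per support vector")
        if (self.weights < -1e-12).any() or (self.weights > self.C + 1e-8).any():
            raise ValueError("dual coefficients must satisfy 0 <= w_n <= C")


def standardize(
    train_matrix: np.ndarray, apply_matrix: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Per-feature z-scoring with training statistics only.

    Returns ``(train_z, apply_z, center, scale)``; a zero-variance feature
    gets scale 1 (with a warning) so it maps to zeros rather than NaN.
    """
    x = np.asarray(train_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2D training matrix with >= 2 rows")
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=0)
    degenerate = scale == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s); scale forced to 1",
            stacklevel=2)
        scale = np.where(degenerate, 1.0, scale)
    train_z = (x - center) / scale
    apply_z = None
    if apply_matrix is not None:
        apply_z = (np.asarray(apply_matrix, dtype=float) - center) / scale
    return train_z, apply_z, center, scale


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              center: np.ndarray | None = None,
              scale: np.ndarray | None = None,
              selected_features: list[int] | None = None,
              tol: float = 1e-3) -> SVMModel:
    """Fit the soft-margin dual with the unit-width Gaussian kernel.

    ``X`` must already be standardized.  The quadratic program is solved by
    scikit-learn's SMO implementation; the returned model exposes the raw
    expansion terms (support vectors, nonnegative weights, labels, bias).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    y_pm = np.where(y == classes.max(), 1, -1)
    clf = SVC(kernel="rbf", gamma=1.0, C=C, tol=tol)
    clf.fit(X, y_pm)
    signed = clf.dual_coef_[0]              # alpha_n * y_n
    labels = np.sign(signed).astype(int)
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        weights=np.abs(signed),
        labels=labels,
        bias=float(clf.intercept_[0]),
        C=C,
        selected_features=list(selected_features or []),
        center=center,
        scale=scale,
    )


def svm_score(model: SVMModel, x: np.ndarray) -> float | np.ndarray:
    """Evaluate ``sum_n w_n y_n exp(-||x_n - x||^2) + b``.

    ``x`` is one standardized feature row (or a 2D batch of rows) over the
    model's selected features.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xb = np.atleast_2d(x)
    if xb.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"expected {model.support_vectors.shape[1]} features, got {xb.shape[1]}")
    d2 = ((xb[:, None, :] - model.support_vectors[None, :, :]) ** 2).sum(axis=2)
    scores = (model.weights * model.labels * np.exp(-d2)).sum(axis=1) + model.bias
    return float(scores[0]) if single else scores


def cv_objective(
    X: np.ndarray,
    y: np.ndarray,
    feature_subset: list[int],
    k_folds: int = 10,
    n_repeats: int = 1,
    seed: int = 0,
    C: float = 1.0,
    metric: str = "accuracy",
) -> float:
    """Mean stratified k-fold CV performance of an SVM on a feature subset.

    Fold assignment is re-randomized ``n_repeats`` times; standardization
    is learned inside each training fold.  Deterministic given ``seed``.
    """
    if len(feature_subset) == 0:
        raise ValueError("feature subset is empty")
    X = np.asarray(X, dtype=float)[:, list(feature_subset)]
    y = np.asarray(y)
    counts = np.bincount(y.astype(int))
    if counts[counts > 0].min() < k_folds:
        raise ValueError(f"k_folds={k_folds} exceeds the smallest class size")

    perf = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed * 100003 + rep)
        for train_idx, test_idx in skf.split(X, y):
            xtr, xte, _, _ = standardize(X[train_idx], X[test_idx])
            model = train_svm(xtr, y[train_idx], C=C)
            scores = svm_score(model, xte)
            if metric == "accuracy":
                pred = (np.atleast_1d(scores) > 0).astype(int)
                perf.append(float((pred == y[test_idx]).mean()))
            elif metric == "auc":
                from radpipe.outcome_stats import roc_auc_and_cutoff
                yt = y[test_idx]
                if yt.min() == yt.max():
                    continue
                perf.append(roc_auc_and_cutoff(np.atleast_1d(scores), yt).auc)
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return float(np.mean(perf))


@dataclass
class SelectionTrace:
    """Per-iteration record of the greedy forward search."""

    chosen: list[int] = field(default_factory=list)
    objective: list[float] = field(default_factory=list)
    candidate_scores: list[dict[int, float]] = field(default_factory=list)
    n_repeats: int = 1


@dataclass(frozen=True)
class SelectionConfig:
    k_folds: int = 10
    n_repeats: int = 50     # scaled-down default; 1000 reproduces the full protocol
    max_features: int = 4
    min_improvement: float = 1e-6
    C: float = 1.0
    metric: str = "accuracy"
    seed: int = 0


def sequential_forward_selection(
    X: np.ndarray, y: np.ndarray, config: SelectionConfig | None = None
) -> tuple[list[int], SelectionTrace, SVMModel]:
    """Greedy forward feature selection maximizing the CV objective.

    At each iteration every remaining candidate is scored by
    :func:`cv_objective` on the current set plus that candidate; the best
    one is added (ties broken toward the lower feature index).  The search
    stops when the best improvement falls below ``min_improvement`` or
    ``max_features`` are selected; the final model is refit on all data
    with the selected subset.
    """
    cfg = config or SelectionConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_features = X.shape[1]
    if n_features < 2:
        raise ValueError("need >= 2 candidate features")

    selected: list[int] = []
    trace = SelectionTrace(n_repeats=cfg.n_repeats)
    best_obj = -np.inf
    while len(selected) < cfg.max_features:
        scores: dict[int, float] = {}
        for j in range(n_features):
            if j in selected:
                continue
            scores[j] = cv_objective(
                X, y, selected + [j], k_folds=cfg.k_folds,
                n_repeats=cfg.n_repeats, seed=cfg.seed, C=cfg.C, metric=cfg.metric)
        # max objective, ties toward the lower index (dict preserves order)
        cand = max(scores, key=lambda j: (scores[j], -j))
        improvement = scores[cand] - (best_obj if np.isfinite(best_obj) else 0.0)
        if selected and improvement < cfg.min_improvement:
            break
        selected.append(cand)
        best_obj = scores[cand]
        trace.chosen.append(cand)
        trace.objective.append(best_obj)
        trace.candidate_scores.append(scores)

    xz, _, center, scale = standardize(X[:, selected])
    model = train_svm(xz, y, C=cfg.C, center=center, scale=scale,
                      selected_features=selected)
    return selected, trace, model


def cross_validated_scores(
    X: np.ndarray, y: np.ndarray, feature_subset: list[int],
    k_folds: int = 10, C: float = 1.0, seed: int = 0,
) -> np.ndarray:
    """Out-of-fold decision score per patient.

    Each patient is scored by the model trained on the folds that do not
    contain them, avoiding resubstitution optimism.
    """
    X = np.asarray(X, dtype=float)[:, list(feature_subset)]
    y = np.asarray(y)
    out = np.empty(len(y))
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        xtr, xte, _, _ = standardize(X[train_idx], X[test_idx])
        model = train_svm(xtr, y[train_idx], C=C)
        out[test_idx] = np.atleast_1d(svm_score(model, xte))
    return out


def refit_scores(X: np.ndarray, y: np.ndarray, feature_subset: list[int],
                 C: float = 1.0) -> np.ndarray:
    """Resubstitution scores from a single model fit on all data."""
    X = np.asarray(X, dtype=float)[:, list(feature_subset)]
    xz, _, center, scale = standardize(X)
    model = train_svm(xz, np.asarray(y), C=C, center=center, scale=scale)
    return np.atleast_1d(svm_score(model, xz))
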
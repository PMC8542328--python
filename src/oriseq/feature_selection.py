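"""Two-step feature selection: score-based ranking, then incremental search.

Features are first ranked — by F-score (between-class separation over
pooled within-class variance) or, for TF-IDF columns, by the fitted model's
own tf-idf weight — and then nested top-j subsets are evaluated with a
cross-validated classifier; the subset size with the highest mean accuracy
wins (smallest size on ties).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from oriseq.feature_extraction import FeatureMatrix, TfIdfModel

#: Replaces a zero pooled within-class variance so perfectly separating
#: constant-within-class features get a large finite score instead of inf.
VARIANCE_EPSILON = 1e-12


@dataclass(frozen=True)
class FeatureScores:
    """Per-feature ranking scores and the induced (stable) descending order."""

    names: list[str]
    scores: np.ndarray
    method: str
    order: np.ndarray  # permutation of feature indices, best first

    def ranked_names(self) -> list[str]:
        return [self.names[i] for i in self.order]


def f_score(matrix: FeatureMatrix, *, eps: float = VARIANCE_EPSILON) -> FeatureScores:
    """Fisher-style F-score of every feature.

    F_i = [(mean_i^+ − mean_i)^2 + (mean_i^− − mean_i)^2] divided by the sum
    of the two within-class sample variances (ddof=1). Zero denominator with
    a nonzero numerator is replaced by ``eps``; zero with zero gives F = 0.
    """
    y = matrix.labels
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"each class needs >= 2 samples for the variance (got {n_pos}+/{n_neg}-)")
    X = matrix.values
    pos, neg = X[y == 1], X[y == 0]
    mean_all = X.mean(axis=0)
    mean_pos, mean_neg = pos.mean(axis=0), neg.mean(axis=0)
    numerator = (mean_pos - mean_all) ** 2 + (mean_neg - mean_all) ** 2
    denominator = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    scores = np.zeros(X.shape[1])
    degenerate = denominator == 0
    ok = ~degenerate
    scores[ok] = numerator[ok] / denominator[ok]
    scores[degenerate & (numerator > 0)] = numerator[degenerate & (numerator > 0)] / eps
    order = np.argsort(-scores, kind="stable")
    return FeatureScores(names=list(matrix.columns), scores=scores,
                         method="f_score", order=order)


def tfidf_score(matrix: FeatureMatrix, model: TfIdfModel) -> FeatureScores:
    """Rank TF-IDF-provenance columns by the fitted model's tfidf weights."""
    from oriseq.feature_extraction import build_vocabulary

    non_tfidf = [c for c in matrix.columns if not c.startswith("tfidf:")]
    if non_tfidf:
        raise ValueError(
            f"tfidf_score requires TF-IDF columns only; offending: {non_tfidf[:5]}")
    vocab = build_vocabulary(model.k_min, model.k_max)
    scores = np.array([model.tfidf[vocab.index[c.split(":", 1)[1]]]
                       for c in matrix.columns])
    order = np.argsort(-scores, kind="stable")
    return FeatureScores(names=list(matrix.columns), scores=scores,
                         method="tfidf_score", order=order)


def rank_features(matrix: FeatureMatrix, method: str = "f_score", *,
                  tfidf_model: TfIdfModel | None = None) -> FeatureScores:
    if method == "f_score":
        return f_score(matrix)
    if method == "tfidf_score":
        if tfidf_model is None:
            raise ValueError("tfidf_score ranking requires a fitted TfIdfModel")
        return tfidf_score(matrix, tfidf_model)
    raise ValueError(f"unknown ranking method {method!r}")


def make_cv_evaluator(folds: int = 5, seed: int = 0,
                      estimator=None) -> Callable[[np.ndarray, np.ndarray], float]:
    """Default IFS inner evaluator: mean stratified CV accuracy of an RBF SVM.

    The fold assignment is seeded once, so the returned callable is
    deterministic and every subset size sees the same folds.
    """
    def evaluate(X: np.ndarray, y: np.ndarray) -> float:
        est = estimator if estimator is not None else SVC(kernel="rbf")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return float(cross_val_score(est, X, y, cv=cv, scoring="accuracy").mean())

    return evaluate


@dataclass(frozen=True)
class SelectionResult:
    """IFS accuracy curve and the chosen feature subset."""

    ranking_method: str
    accuracy_curve: list[tuple[int, float]]
    best_count: int
    selected: list[str]

    def best_accuracy(self) -> float:
        return dict(self.accuracy_curve)[self.best_count]

    def to_files(self, curve_path: str | os.PathLike,
                 features_path: str | os.PathLike) -> None:
        with open(curve_path, "w") as fh:
            fh.write("feature_count\taccuracy\n")
            for count, acc in self.accuracy_curve:
                fh.write(f"{count}\t{acc:.17e}\n")
        with open(features_path, "w") as fh:
            fh.write("\n".join(self.selected) + "\n")


def incremental_feature_selection(
    matrix: FeatureMatrix,
    scores: FeatureScores,
    evaluator: Callable[[np.ndarray, np.ndarray], float] | None = None,
    *,
    max_count: int | None = None,
    step: int = 1,
) -> SelectionResult:
    """Evaluate nested top-j feature subsets in ranking order.

    Subset sizes are 1, 1+step, 1+2·step, … capped at ``max_count`` (which
    is always included as the final size). Ties on the maximum accuracy go
    to the smallest size. The curve depends only on the ranking and the
    evaluator; unselected columns never enter a fit.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    if scores.names != matrix.columns:
        raise ValueError("scores are not aligned with the matrix columns")
    total = matrix.n_features
    limit = total if max_count is None else min(max_count, total)
    if limit < 1:
        raise ValueError("max_count must be >= 1")
    sizes = list(range(1, limit + 1, step))
    if sizes[-1] != limit:
        sizes.append(limit)
    if evaluator is None:
        evaluator = make_cv_evaluator()

    ranked = scores.ranked_names()
    y = matrix.labels
    curve: list[tuple[int, float]] = []
    best_count, best_acc = sizes[0], -np.inf
    for size in sizes:
        X = matrix.select_columns(ranked[:size]).values
        acc = float(evaluator(X, y))
        if not np.isfinite(acc):
            raise ValueError(f"evaluator returned non-finite accuracy at "
                             f"subset size {size}")
        curve.append((size, acc))
        if acc > best_acc:
            best_count, best_acc = size, acc
    return SelectionResult(ranking_method=scores.method, accuracy_curve=curve,
                           best_count=best_count, selected=ranked[:best_count])
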
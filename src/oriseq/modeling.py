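"""Classifier training, repeated cross-validated evaluation and transfer.

Metrics follow the origin-prediction convention: the confusion state is
``(n_pos, n_neg, fn, fp)`` where ``fn`` is the number of positive sequences
misjudged negative and ``fp`` the number of negatives misjudged positive.
Sensitivity, specificity, accuracy and MCC are derived from those four
counts; AUC comes from ranked decision scores.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import GradientBoostingClassifier

from oriseq.feature_extraction import FeatureMatrix, FeaturePipeline
from oriseq.sequence_io import LabeledSequenceSet

ARCHIVE_VERSION = 1

# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_degenerate: bool = False


def compute_metrics(confusion: tuple[int, int, int, int]) -> Metrics:
    """Sn/Sp/Acc/MCC from ``(n_pos, n_neg, false_neg, false_pos)``.

    MCC uses the ratio form
    ``[1 − (fn/n⁺ + fp/n⁻)] / sqrt((1 + (fp−fn)/n⁺)(1 + (fn−fp)/n⁻))``,
    algebraically equal to the standard confusion-matrix MCC. A zero
    denominator (a degenerate confusion) reports MCC = 0 with a flag.
    """
    n_pos, n_neg, fn, fp = confusion
    if min(n_pos, n_neg, fn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present (n_pos, n_neg > 0)")
    if fn > n_pos or fp > n_neg:
        raise ValueError("false counts cannot exceed class sizes")
    sn = 1.0 - fn / n_pos
    sp = 1.0 - fp / n_neg
    acc = 1.0 - (fn + fp) / (n_pos + n_neg)
    inner = (1.0 + (fp - fn) / n_pos) * (1.0 + (fn - fp) / n_neg)
    if inner <= 0:
        # inner == 0 iff a predicted class is empty; never negative.
        return Metrics(sn=sn, sp=sp, acc=acc, mcc=0.0, mcc_degenerate=True)
    mcc = (1.0 - (fn / n_pos + fp / n_neg)) / math.sqrt(inner)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def compute_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve from decision scores (ties averaged)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(labels, scores))


# ---------------------------------------------------------------------------
# Classifier families and hyperparameter grids
# ---------------------------------------------------------------------------

#: family -> hyperparameter names accepted in a grid
_FAMILY_PARAMS: dict[str, tuple[str, ...]] = {
    "svm": ("C", "gamma"),
    "mlp": ("alpha",),
    "knn": ("n_neighbors",),
    "decision_tree": ("min_samples_split", "max_depth"),
    "naive_bayes": (),
    "gradient_boosted_trees": ("n_estimators", "learning_rate"),
}


def default_grid(family: str) -> dict[str, list]:
    """The published tuning grid for each classifier family.

    SVM cost / kernel-width ranges are log2 grids: cost exponents −5..15 in
    steps of 2, width exponents −15..−5 in steps of 1. Families without a
    published grid (KNN, naive Bayes) get a single default point.
    """
    if family == "svm":
        return {"C": [2.0 ** e for e in range(-5, 16, 2)],
                "gamma": [2.0 ** e for e in range(-15, -4)]}
    if family == "mlp":
        return {"alpha": [0.001, 0.01, 0.1, 0.5, 1, 1.5]}
    if family == "decision_tree":
        return {"min_samples_split": list(range(2, 31, 2)),
                "max_depth": list(range(1, 11))}
    if family == "gradient_boosted_trees":
        return {"n_estimators": list(range(10, 1001, 50)),
                "learning_rate": [round(0.1 * i, 1) for i in range(1, 11)]}
    if family == "knn":
        return {"n_neighbors": [5]}
    if family == "naive_bayes":
        return {}
    raise ValueError(f"unknown classifier family {family!r}")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid."""

    family: str
    grid: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown classifier family {self.family!r}; "
                             f"known: {sorted(_FAMILY_PARAMS)}")
        if not self.grid:
            object.__setattr__(self, "grid", default_grid(self.family))
        allowed = set(_FAMILY_PARAMS[self.family])
        unknown = set(self.grid) - allowed
        if unknown:
            raise ValueError(f"unknown hyperparameter(s) for {self.family}: "
                             f"{sorted(unknown)}")
        for name, values in self.grid.items():
            if not values:
                raise ValueError(f"empty value list for hyperparameter {name!r}")

    def grid_points(self) -> list[dict]:
        """Grid points in declared order (first key varies slowest)."""
        import itertools
        keys = list(self.grid)
        if not keys:
            return [{}]
        return [dict(zip(keys, combo))
                for combo in itertools.product(*(self.grid[k] for k in keys))]


def make_estimator(family: str, params: dict | None = None, *, seed: int = 0):
    """Instantiate the sklearn estimator behind a family name.

    MLP: one hidden layer of 100 rectifier units, 1000-iteration cap,
    seeded initialization; only alpha is tuned.
    """
    params = dict(params or {})
    if family == "svm":
        return SVC(kernel="rbf", random_state=seed, **params)
    if family == "mlp":
        return MLPClassifier(hidden_layer_sizes=(100,), activation="relu",
                             max_iter=1000, random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(**({"n_neighbors": 5} | params))
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "naive_bayes":
        return GaussianNB(**params)
    if family == "gradient_boosted_trees":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier family {family!r}")


def _decision_scores(estimator, X: np.ndarray) -> np.ndarray:
    """Continuous scores for ranking: decision function if available, else
    positive-class probability."""
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=float)
    proba = estimator.predict_proba(X)
    pos_col = list(estimator.classes_).index(1)
    return np.asarray(proba[:, pos_col], dtype=float)


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------


def tune_hyperparameters(
    spec: ClassifierSpec,
    matrix: FeatureMatrix,
    *,
    folds: int = 5,
    seed: int = 0,
) -> tuple[dict, float, pd.DataFrame]:
    """Exhaustive grid search by mean stratified-CV accuracy.

    One fold assignment (seeded) is shared by every candidate; ties go to
    the earlier grid point. Returns ``(best_params, best_accuracy, table)``.
    """
    if matrix.n_samples == 0:
        raise ValueError("empty feature matrix")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(matrix.values, matrix.labels))
    rows = []
    best_params: dict | None = None
    best_acc = -np.inf
    for params in spec.grid_points():
        accs = []
        for train_idx, test_idx in splits:
            est = make_estimator(spec.family, params, seed=seed)
            est.fit(matrix.values[train_idx], matrix.labels[train_idx])
            pred = est.predict(matrix.values[test_idx])
            accs.append(float((pred == matrix.labels[test_idx]).mean()))
        mean_acc = float(np.mean(accs))
        rows.append({**params, "cv_accuracy": mean_acc})
        if mean_acc > best_acc:
            best_params, best_acc = params, mean_acc
    return best_params, best_acc, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationReport:
    """Per-repeat metrics (pooled over each repeat's folds) with summaries."""

    per_repeat: pd.DataFrame  # columns: repeat, n_pos, n_neg, fn, fp, sn, sp, acc, mcc, auc
    folds: int
    repeats: int
    seed: int

    @property
    def mean(self) -> dict[str, float]:
        cols = ["sn", "sp", "acc", "mcc", "auc"]
        return {c: float(self.per_repeat[c].mean()) for c in cols}

    @property
    def std(self) -> dict[str, float]:
        cols = ["sn", "sp", "acc", "mcc", "auc"]
        ddof = 1 if len(self.per_repeat) > 1 else 0
        return {c: float(self.per_repeat[c].std(ddof=ddof)) for c in cols}

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.per_repeat.to_csv(path, sep="\t", index=False, float_format="%.17e")

    def summary(self) -> str:
        m, s = self.mean, self.std
        lines = [
            f"{self.repeats} x {self.folds}-fold cross-validation (seed {self.seed})",
            "metric\tmean\tstd",
        ]
        for name, col in (("Acc", "acc"), ("Sn", "sn"), ("Sp", "sp"),
                          ("MCC", "mcc"), ("AUC", "auc")):
            lines.append(f"{name}\t{m[col]:.4f}\t{s[col]:.4f}")
        return "\n".join(lines)


def _evaluate_predictions(y: np.ndarray, pred: np.ndarray,
                          scores: np.ndarray) -> dict[str, float]:
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    fn = int(((y == 1) & (pred == 0)).sum())
    fp = int(((y == 0) & (pred == 1)).sum())
    m = compute_metrics((n_pos, n_neg, fn, fp))
    return {"n_pos": n_pos, "n_neg": n_neg, "fn": fn, "fp": fp,
            "sn": m.sn, "sp": m.sp, "acc": m.acc, "mcc": m.mcc,
            "auc": compute_auc(y, scores)}


def repeated_cv(
    spec: ClassifierSpec | str,
    matrix: FeatureMatrix | None = None,
    *,
    params: dict | None = None,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    pipeline: FeaturePipeline | None = None,
    sequences: LabeledSequenceSet | None = None,
) -> EvaluationReport:
    """Repeated stratified k-fold evaluation.

    Each repeat draws an independent fold assignment seeded from the master
    seed. Per repeat, fold confusions and decision scores are pooled before
    computing the metrics, which are then averaged over repeats.

    When ``pipeline`` and ``sequences`` are given, the feature pipeline is
    refit on each fold's training split before transforming the held-out
    fold, so data-dependent encoders (TF-IDF) never see test sequences.
    Otherwise a precomputed ``matrix`` is used directly.
    """
    family = spec.family if isinstance(spec, ClassifierSpec) else spec
    if family not in _FAMILY_PARAMS:
        raise ValueError(f"unknown classifier family {family!r}")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    fold_safe = pipeline is not None
    if fold_safe:
        if sequences is None:
            raise ValueError("fold-safe mode needs the sequence set")
        y = sequences.labels
        n = len(sequences)
    else:
        if matrix is None:
            raise ValueError("either a matrix or (pipeline, sequences) is required")
        y = matrix.labels
        n = matrix.n_samples
    for cls in (0, 1):
        if int((y == cls).sum()) < folds:
            raise ValueError(f"class {cls} has fewer members than folds={folds}")

    master = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                    master.spawn(repeats)]
    rows = []
    for rep, rep_seed in enumerate(repeat_seeds):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        pooled_pred = np.empty(n, dtype=int)
        pooled_scores = np.empty(n, dtype=float)
        for train_idx, test_idx in cv.split(np.zeros(n), y):
            if fold_safe:
                pipe = FeaturePipeline(
                    methods=list(pipeline.methods), k_min=pipeline.k_min,
                    k_max=pipeline.k_max,
                    pseknc_configs=pipeline.pseknc_configs,
                    selected_columns=pipeline.selected_columns)
                X_train = pipe.fit_transform(sequences.subset(train_idx)).values
                X_test = pipe.transform(sequences.subset(test_idx)).values
            else:
                X_train = matrix.values[train_idx]
                X_test = matrix.values[test_idx]
            est = make_estimator(family, params, seed=rep_seed)
            est.fit(X_train, y[train_idx])
            pooled_pred[test_idx] = est.predict(X_test)
            pooled_scores[test_idx] = _decision_scores(est, X_test)
        rows.append({"repeat": rep,
                     **_evaluate_predictions(y, pooled_pred, pooled_scores)})
    return EvaluationReport(per_repeat=pd.DataFrame(rows), folds=folds,
                            repeats=repeats, seed=seed)


# ---------------------------------------------------------------------------
# Final models, persistence, cross-species transfer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesProfile:
    """The per-species recipe: features, ranking, classifier, tuned params."""

    species: str
    feature_method: str | list[str]
    ranking_method: str = "f_score"
    classifier_family: str = "mlp"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier_family not in _FAMILY_PARAMS:
            raise ValueError(f"unknown classifier family "
                             f"{self.classifier_family!r}")


@dataclass
class OriginModel:
    """A trained classifier bundled with its frozen feature pipeline."""

    profile: SpeciesProfile
    pipeline: FeaturePipeline
    estimator: Any
    version: int = ARCHIVE_VERSION

    def predict(self, seq_set: LabeledSequenceSet) -> np.ndarray:
        X = self.pipeline.transform(seq_set).values
        return np.asarray(self.estimator.predict(X))

    def decision_scores(self, seq_set: LabeledSequenceSet) -> np.ndarray:
        X = self.pipeline.transform(seq_set).values
        return _decision_scores(self.estimator, X)

    def save(self, path: str | os.PathLike) -> None:
        joblib.dump({"version": self.version, "profile": self.profile,
                     "pipeline": self.pipeline, "estimator": self.estimator},
                    path)

    @staticmethod
    def load(path: str | os.PathLike) -> "OriginModel":
        try:
            payload = joblib.load(path)
        except Exception as exc:
            raise ValueError(f"cannot load model archive {path}: {exc}") from exc
        if not isinstance(payload, dict) or "version" not in payload:
            raise ValueError(f"{path}: not an origin-model archive")
        if payload["version"] != ARCHIVE_VERSION:
            raise ValueError(f"{path}: archive version {payload['version']} "
                             f"incompatible with {ARCHIVE_VERSION}")
        return OriginModel(profile=payload["profile"],
                           pipeline=payload["pipeline"],
                           estimator=payload["estimator"],
                           version=payload["version"])


def train_final(
    profile: SpeciesProfile,
    pipeline: FeaturePipeline,
    train: LabeledSequenceSet,
    *,
    seed: int = 0,
) -> OriginModel:
    """Fit the pipeline and classifier on the full training set."""
    if len(train) == 0:
        raise ValueError("empty training set")
    matrix = pipeline.fit_transform(train)
    est = make_estimator(profile.classifier_family, profile.hyperparameters,
                         seed=seed)
    est.fit(matrix.values, matrix.labels)
    return OriginModel(profile=profile, pipeline=pipeline, estimator=est)


def cross_species_evaluate(model: OriginModel,
                           target: LabeledSequenceSet) -> EvaluationReport:
    """Score a target species with a frozen source-species model.

    The target sequences pass through the source pipeline exactly as fitted
    (vocabulary, TF-IDF weights, selected columns); no component is refit.
    Returns a single-shot report (one "repeat", no folds).
    """
    if not model.pipeline.is_fitted:
        raise ValueError("model pipeline is missing frozen components")
    y = target.labels
    pred = model.predict(target)
    scores = model.decision_scores(target)
    row = {"repeat": 0, **_evaluate_predictions(y, pred, scores)}
    return EvaluationReport(per_repeat=pd.DataFrame([row]), folds=1,
                            repeats=1, seed=0)
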
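"""Nested cross-validated classification of bradykinesia.

Six classifier families (logistic regression, SVM, random forest, decision
tree, gradient-boosted trees, k-nearest neighbours) are tuned and evaluated
in a nested scheme: a stratified 5-fold outer loop estimates generalization
performance; within each outer training set a stratified 3-fold inner grid
search selects hyperparameters by mean accuracy. The inner search never
sees outer-test rows; scale-sensitive families are standardized with a
scaler fit on the outer-train subset only. Fold metrics are summarized
with t-distribution 95% confidence intervals (df = folds - 1), and feature
influence is ranked by a sampling Shapley estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from lightgbm import LGBMClassifier
from scipy import stats
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)

from .shapley import mean_abs_attribution, sampling_shapley

FAMILIES = ("LR", "SVM", "RF", "DT", "LGBM", "KNN")

#: Families whose distance/margin geometry needs standardized inputs.
_SCALED = {"LR", "SVM", "KNN"}

DEFAULT_GRIDS: dict[str, list[dict] | dict] = {
    "LR": {"clf__C": [0.01, 0.1, 1, 10]},
    "SVM": [
        {"clf__kernel": ["rbf"], "clf__C": [0.1, 1, 10, 100],
         "clf__gamma": ["scale", 0.01, 0.1]},
        {"clf__kernel": ["linear"], "clf__C": [0.1, 1, 10, 100]},
    ],
    "RF": {"clf__n_estimators": [100, 300], "clf__max_depth": [None, 3, 5]},
    "DT": {"clf__max_depth": [None, 3, 5, 10]},
    "LGBM": {"clf__learning_rate": [0.05, 0.1], "clf__n_estimators": [100, 300]},
    "KNN": {"clf__n_neighbors": [3, 5, 7, 9]},
}


class SingleClassError(ValueError):
    """AUC is undefined when the truth contains a single class."""


@dataclass
class CVConfig:
    """Nested cross-validation configuration for one model family."""

    model_family: str = "SVM"
    outer_folds: int = 5
    inner_folds: int = 3
    hyperparameter_grid: list[dict] | dict | None = None
    seed: int = 0
    compute_importances: bool = True
    shapley_permutations: int = 30
    shapley_max_instances: int = 40

    def __post_init__(self) -> None:
        if self.model_family not in FAMILIES:
            raise ValueError(f"unknown family {self.model_family!r}; one of {FAMILIES}")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if self.hyperparameter_grid is None:
            self.hyperparameter_grid = DEFAULT_GRIDS[self.model_family]
        if not self.hyperparameter_grid:
            raise ValueError("hyperparameter grid must be non-empty")


@dataclass
class FoldResult:
    fold_index: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    train_auc: float
    chosen_hyperparameters: dict
    test_indices: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    roc: tuple[np.ndarray, np.ndarray] | None = field(repr=False, default=None)

    def metrics(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "train_auc": self.train_auc,
        }


@dataclass
class MetricSummary:
    """Mean, SD and t-based 95% CI of a metric across outer folds."""

    metric: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass
class ModelReport:
    family: str
    folds: list[FoldResult]
    summaries: dict[str, MetricSummary]
    feature_importances: list[tuple[str, float]]
    seed: int

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "seed": self.seed,
            "folds": [
                {
                    "fold_index": f.fold_index,
                    **f.metrics(),
                    "chosen_hyperparameters": {
                        k: (v if isinstance(v, (int, float, str, type(None))) else str(v))
                        for k, v in f.chosen_hyperparameters.items()
                    },
                    "roc": None if f.roc is None else
                        {"fpr": f.roc[0].tolist(), "tpr": f.roc[1].tolist()},
                }
                for f in self.folds
            ],
            "summary": {
                m: {"mean": s.mean, "sd": s.sd, "ci": [s.ci_low, s.ci_high]}
                for m, s in self.summaries.items()
            },
            "importances": [[n, float(v)] for n, v in self.feature_importances],
        }


def make_estimator(family: str, seed: int = 0) -> Pipeline:
    """Build the family's pipeline; scale-sensitive families get a scaler."""
    if family == "LR":
        clf = LogisticRegression(max_iter=5000, random_state=seed)
    elif family == "SVM":
        clf = SVC(random_state=seed)
    elif family == "RF":
        clf = RandomForestClassifier(random_state=seed)
    elif family == "DT":
        clf = DecisionTreeClassifier(random_state=seed)
    elif family == "LGBM":
        clf = LGBMClassifier(random_state=seed, verbose=-1)
    elif family == "KNN":
        clf = KNeighborsClassifier()
    else:
        raise ValueError(f"unknown family {family!r}")
    steps = []
    if family in _SCALED:
        steps.append(("scaler", StandardScaler()))
    steps.append(("clf", clf))
    return Pipeline(steps)


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score: probability if available, else margin distance."""
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1]
        except AttributeError:  # pragma: no cover
            pass
    return model.decision_function(X)


def stratified_kfold(labels: Sequence[int], k: int, seed: int = 0) -> np.ndarray:
    """Assign each subject to one of k stratified folds.

    Folds partition the subjects; per-fold class counts differ from exact
    proportionality by at most 1.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def compute_metrics(
    y_true: Sequence[int], y_pred: Sequence[int], scores: Sequence[float]
) -> dict[str, float]:
    """Accuracy, precision, recall, F1 (positive class = bradykinesia = 1)
    and rank-based AUC with midrank tie handling."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("truth, predictions and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        raise SingleClassError("AUC undefined: truth contains a single class")
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "auc": float(roc_auc_score(y_true, scores)),
    }


def summarize_metric(values: Sequence[float], metric: str = "") -> MetricSummary:
    """Mean, n-1 SD and 95% CI: mean +/- t(0.975, n-1) * sd / sqrt(n)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("need >= 2 fold values to summarize")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    return MetricSummary(metric=metric, mean=mean, sd=sd,
                         ci_low=mean - half, ci_high=mean + half)


def _inner_splits(
    y_train: np.ndarray, inner_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Explicit stratified inner splits of the outer-train subset.

    A degenerate split (single-class inner-train) is re-drawn once with a
    shifted seed before failing.
    """
    for attempt, s in enumerate((seed, seed + 104729)):
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=s)
        splits = list(skf.split(np.zeros(len(y_train)), y_train))
        if all(len(np.unique(y_train[tr])) == 2 for tr, _ in splits):
            return splits
    raise ValueError("inner split degenerate: a fold's training part is single-class")


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: CVConfig,
    feature_names: Sequence[str] | None = None,
    audit: Callable[..., None] | None = None,
) -> ModelReport:
    """Run the nested cross-validation protocol for one model family.

    For each outer fold the hyperparameter grid is searched by mean inner-CV
    accuracy on the outer-train subset only, the best configuration is refit
    on the full outer-train set, and metrics are computed on the held-out
    outer-test set; train_auc on the outer-train set probes overfitting.
    ``audit``, when given, is called with every index set the procedure
    touches (kind, fold, and arrays), allowing leakage assertions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    rng = np.random.SeedSequence(config.seed)
    split_seed, model_seed, shap_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in rng.spawn(3)
    ]

    assignment = stratified_kfold(y, config.outer_folds, seed=split_seed)
    folds: list[FoldResult] = []
    fitted: list = []
    attributions = []
    for fold in range(config.outer_folds):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        if audit is not None:
            audit(kind="outer", fold=fold, train=train_idx, test=test_idx)
        inner = _inner_splits(y[train_idx], config.inner_folds, split_seed + fold)
        if audit is not None:
            for tr, va in inner:
                audit(kind="inner", fold=fold, train=train_idx[tr], val=train_idx[va])
        est = make_estimator(config.model_family, seed=model_seed)
        search = GridSearchCV(
            est, config.hyperparameter_grid, scoring="accuracy", cv=inner, refit=True
        )
        search.fit(X[train_idx], y[train_idx])
        model = search.best_estimator_
        fitted.append((model, train_idx))

        y_pred = model.predict(X[test_idx])
        s_test = decision_scores(model, X[test_idx])
        m = compute_metrics(y[test_idx], y_pred, s_test)
        train_auc = float(roc_auc_score(y[train_idx], decision_scores(model, X[train_idx])))
        fpr, tpr, _ = roc_curve(y[test_idx], s_test)
        folds.append(
            FoldResult(
                fold_index=fold,
                **m,
                train_auc=train_auc,
                chosen_hyperparameters=dict(search.best_params_),
                test_indices=test_idx,
                roc=(fpr, tpr),
            )
        )
        if config.compute_importances:
            shap_rng = np.random.default_rng(shap_seed + fold)
            n_inst = min(config.shapley_max_instances, len(train_idx))
            inst = X[shap_rng.choice(train_idx, size=n_inst, replace=False)]
            attributions.append(
                sampling_shapley(
                    lambda Z, mdl=model: decision_scores(mdl, Z),
                    background=X[train_idx],
                    instances=inst,
                    n_permutations=config.shapley_permutations,
                    rng=shap_rng,
                )
            )

    names = list(feature_names)
    if config.compute_importances:
        imp = np.mean([mean_abs_attribution(a) for a in attributions], axis=0)
        order = np.argsort(-imp)
        importances = [(names[j], float(imp[j])) for j in order]
    else:
        importances = []
    summaries = {
        m: summarize_metric([f.metrics()[m] for f in folds], metric=m)
        for m in ("accuracy", "precision", "recall", "f1", "auc", "train_auc")
    }
    return ModelReport(
        family=config.model_family,
        folds=folds,
        summaries=summaries,
        feature_importances=importances,
        seed=config.seed,
    )


def evaluate_families(
    X: np.ndarray,
    y: np.ndarray,
    families: Sequence[str] = FAMILIES,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    **config_kwargs,
) -> dict[str, ModelReport]:
    """Nested-CV every requested family with a shared master seed."""
    return {
        fam: nested_cv(
            X, y,
            CVConfig(model_family=fam, seed=seed, **config_kwargs),
            feature_names=feature_names,
        )
        for fam in families
    }
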
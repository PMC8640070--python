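"""Nested-CV benchmarking, hold-out/external validation and decision curves.

The evaluation grid crosses the seven selection criteria, a ladder of
feature counts and seven classifier families.  Each cell is scored by
stratified 5x2 nested cross-validation on the training data (outer folds
estimate generalisation, inner folds tune hyperparameters by mean AUC).
Per classifier family the cell with the maximal mean outer-fold AUC wins
(ties: fewer features, then criterion name); the winner is re-tuned on
the whole training set and scored on the hold-out and external cohorts.

Classification metrics use the 0.5 probability threshold; AUC is the
rank statistic with midrank ties.  Decision-curve analysis reports the
net benefit NB(p_t) = TP/N - (FP/N) * p_t / (1 - p_t) of acting on
score >= p_t, against treat-all and treat-none references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .io import DosageMatrix

METRICS = ("auc", "accuracy", "precision", "recall", "f1")
PHASES = ("cv", "holdout", "external")

#: default hyperparameter grids per classifier family
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {
        "max_features": [1, 10, 20, 30, 40, 50, 60, 70],
        "max_depth": [1, 2],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [2, 3, 4, 5],
    },
    "XGBoost": {
        "n_estimators": [100, 200, 300, 400],
        "learning_rate": [0.1, 0.5, 1.0],
        "max_depth": [1, 2],
        "min_child_weight": [1, 3],
    },
    "RF": {
        "n_estimators": [100, 200, 300, 400],
        "max_depth": [1, 2],
        "max_features": [1, 10, 20, 30, 40, 50, 60, 70],
        "min_samples_leaf": [2, 3, 4, 5],
        "min_samples_split": [2, 5, 10],
    },
    "AdaBoost": {"n_estimators": [100, 200, 300, 400], "learning_rate": [0.1, 0.5, 1.0]},
    "LR": {"C": [0.01, 0.1, 1, 10]},
    "KNN": {"n_neighbors": [1, 3, 5]},
    "NB": {},
}


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameter grid."""

    name: str
    grid: dict[str, list] = field(default_factory=dict)

    @classmethod
    def default(cls, name: str) -> "ModelSpec":
        if name not in DEFAULT_GRIDS:
            raise ValueError(f"unknown model {name!r}; expected one of {tuple(DEFAULT_GRIDS)}")
        return cls(name, {k: list(v) for k, v in DEFAULT_GRIDS[name].items()})

    def build(self, seed: int):
        n = self.name
        if n == "LR":
            return LogisticRegression(max_iter=2000, random_state=seed)
        if n == "AdaBoost":
            return AdaBoostClassifier(random_state=seed)
        if n == "XGBoost":
            # fixed regularisers; learning rate is searched via the grid
            return XGBClassifier(
                gamma=2,
                reg_lambda=0.5,
                reg_alpha=0.5,
                eval_metric="logloss",
                n_jobs=1,
                tree_method="hist",
                random_state=seed,
                verbosity=0,
            )
        if n == "RF":
            return RandomForestClassifier(random_state=seed, n_jobs=1)
        if n == "KNN":
            return KNeighborsClassifier()
        if n == "DT":
            return DecisionTreeClassifier(random_state=seed)
        if n == "NB":
            return GaussianNB()
        raise ValueError(f"unknown model {n!r}")

    def grid_for(self, n_features: int) -> dict[str, list]:
        """Grid with max_features values above the cell's feature count removed."""
        out = {}
        for k, v in self.grid.items():
            if k == "max_features":
                vv = [x for x in v if x <= n_features]
                out[k] = vv if vv else [n_features]
            else:
                out[k] = list(v)
        return out


@dataclass
class EvalRecord:
    """One (model x criterion x n_features) cell of the results grid."""

    model: str
    criterion: str
    n_features: int
    params: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)  # phase -> metric -> value
    features: list[str] = field(default_factory=list)

    @property
    def cv_auc(self) -> float:
        return self.metrics.get("cv", {}).get("auc", float("nan"))


@dataclass
class DecisionCurve:
    """Net benefit per threshold for one scored model plus references."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self, model: str = "model") -> pd.DataFrame:
        rows = []
        for name, nb in (
            (model, self.net_benefit),
            ("treat_all", self.treat_all),
            ("treat_none", self.treat_none),
        ):
            for t, v in zip(self.thresholds, nb):
                rows.append((float(t), name, float(v)))
        return pd.DataFrame(rows, columns=["threshold", "model", "net_benefit"])


# ---------------------------------------------------------------------------
# splits and metrics


def split_holdout(matrix: DosageMatrix, frac: float, seed: int) -> tuple[DosageMatrix, DosageMatrix]:
    """Class-stratified random split into (train, holdout); disjoint, exhaustive."""
    if not 0 < frac < 1:
        raise ValueError("holdout fraction must be in (0, 1)")
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=frac, random_state=int(seed))
    train_idx, hold_idx = next(splitter.split(np.zeros(matrix.n), matrix.label))
    if len(train_idx) == 0 or len(hold_idx) == 0:
        raise ValueError("degenerate split: one side is empty")
    return matrix.subset(np.sort(train_idx)), matrix.subset(np.sort(hold_idx))


def compute_metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """AUC plus threshold-0.5 accuracy/precision/recall/F1 (0 when undefined)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "accuracy": float((pred == labels).mean()),
        "precision": precision,
        "recall": recall,
        "f1": f1,
    }


def net_benefit(
    scores: np.ndarray, labels: np.ndarray, thresholds: Sequence[float]
) -> DecisionCurve:
    """Decision-curve analysis over a threshold grid in (0, 1)."""
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if np.any(thresholds <= 0) or np.any(thresholds >= 1):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    odds = thresholds / (1 - thresholds)
    nb = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tp = ((pred) & (labels == 1)).sum()
        fp = ((pred) & (labels == 0)).sum()
        nb[i] = tp / n - (fp / n) * odds[i]
    prev = labels.mean()
    treat_all = prev - (1 - prev) * odds
    return DecisionCurve(thresholds, nb, treat_all, np.zeros_like(thresholds))


def default_thresholds() -> np.ndarray:
    """The studied population's plausible range: p_t in [0.25, 0.75]."""
    return np.round(np.arange(0.25, 0.7501, 0.05), 4)


# ---------------------------------------------------------------------------
# nested CV and tuning


def _inner_search(spec: ModelSpec, X: np.ndarray, y: np.ndarray, inner: int, seed: int):
    """Grid search by mean inner-fold AUC; returns a fitted best estimator + params."""
    est = spec.build(seed)
    grid = spec.grid_for(X.shape[1])
    if not grid:
        est.fit(X, y)
        return est, {}
    cv = StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, refit=True, n_jobs=1)
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


def nested_cv(
    spec: ModelSpec,
    features: Sequence[str],
    train: DosageMatrix,
    outer: int = 5,
    inner: int = 2,
    seed: int = 0,
) -> list[dict[str, float]]:
    """Stratified outer-fold metrics with inner-fold hyperparameter tuning."""
    if len(np.unique(train.label)) < 2:
        raise ValueError("training data contains a single class")
    X = train.select_features(features)
    y = train.label
    folds = StratifiedKFold(n_splits=outer, shuffle=True, random_state=int(seed))
    per_fold = []
    for k, (tr, te) in enumerate(folds.split(X, y)):
        best, _ = _inner_search(spec, X[tr], y[tr], inner, int(seed) + 1000 + k)
        scores = best.predict_proba(X[te])[:, 1]
        per_fold.append(compute_metrics(scores, y[te]))
    return per_fold


def mean_metrics(per_fold: list[dict[str, float]]) -> dict[str, float]:
    return {m: float(np.mean([f[m] for f in per_fold])) for m in per_fold[0]}


def tune_final(
    spec: ModelSpec, features: Sequence[str], train: DosageMatrix, inner: int = 2, seed: int = 0
):
    """Grid-tune on the full training set and return (fitted model, params)."""
    X = train.select_features(features)
    est, params = _inner_search(spec, X, train.label, inner, int(seed))
    return est, params


# ---------------------------------------------------------------------------
# the full evaluation grid


def _check_external(external: DosageMatrix | None, features: Sequence[str]) -> None:
    if external is None:
        return
    missing = [f for f in features if f not in external.feature_names]
    if missing:
        raise ValueError(f"external cohort lacks features: {missing}")


def run_grid(
    train: DosageMatrix,
    holdout: DosageMatrix,
    external: DosageMatrix | None,
    rankings: Mapping[str, Sequence[str]],
    feature_grid: Sequence[int],
    models: Sequence[str] = tuple(DEFAULT_GRIDS),
    outer: int = 5,
    inner: int = 2,
    seed: int = 0,
    grids: Mapping[str, dict] | None = None,
    no_fs_arm: bool = False,
) -> tuple[list[EvalRecord], dict[str, EvalRecord], EvalRecord]:
    """Evaluate every (criterion x n_features x model) cell.

    ``rankings`` maps criterion name -> ordered feature list (from the
    aggregation stage, computed on the training data only).  Returns all
    records, the best record per model family (max mean CV AUC, ties by
    fewer features then criterion name) with hold-out/external metrics
    filled in, and the overall best.
    """
    if not rankings or not feature_grid or not models:
        raise ValueError("empty evaluation grid")
    arms: list[tuple[str, Sequence[str]]] = sorted(rankings.items())
    if no_fs_arm:
        arms.append(("none", list(train.feature_names)))
    records: list[EvalRecord] = []
    for model_name in models:
        spec = (
            ModelSpec(model_name, dict(grids[model_name]))
            if grids and model_name in grids
            else ModelSpec.default(model_name)
        )
        for criterion, ranked in arms:
            counts = list(feature_grid) if criterion != "none" else [len(ranked)]
            for n_feat in counts:
                if n_feat > len(ranked):
                    raise ValueError(
                        f"{criterion} ranking has {len(ranked)} features, needed {n_feat}"
                    )
                feats = list(ranked[:n_feat])
                per_fold = nested_cv(spec, feats, train, outer, inner, seed)
                records.append(
                    EvalRecord(
                        model=model_name,
                        criterion=criterion,
                        n_features=n_feat,
                        metrics={"cv": mean_metrics(per_fold)},
                        features=feats,
                    )
                )
    best_per_model: dict[str, EvalRecord] = {}
    for model_name in models:
        cands = [r for r in records if r.model == model_name]
        best = max(cands, key=lambda r: (r.cv_auc, -r.n_features, _neg_name(r.criterion)))
        spec = (
            ModelSpec(model_name, dict(grids[model_name]))
            if grids and model_name in grids
            else ModelSpec.default(model_name)
        )
        _check_external(external, best.features)
        fitted, params = tune_final(spec, best.features, train, inner, seed)
        best.params = params
        Xh = holdout.select_features(best.features)
        best.metrics["holdout"] = compute_metrics(fitted.predict_proba(Xh)[:, 1], holdout.label)
        if external is not None:
            Xe = external.select_features(best.features)
            best.metrics["external"] = compute_metrics(
                fitted.predict_proba(Xe)[:, 1], external.label
            )
        best_per_model[model_name] = best
    overall = max(
        best_per_model.values(), key=lambda r: (r.cv_auc, -r.n_features, _neg_name(r.criterion))
    )
    return records, best_per_model, overall


class _neg_name(str):
    """Reverses lexicographic comparison so max() prefers the *smaller* name."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
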
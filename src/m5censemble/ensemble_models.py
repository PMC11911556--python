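"""The eight bagging/boosting classifiers and their evaluation protocols.

Bagging family: random forest (RF), extra trees (ETC), a single
decision tree (DT, the degenerate one-member ensemble) and a bagging
classifier over decision trees (BC). Boosting family: gradient
boosting (GB), histogram-based gradient boosting (HGB), AdaBoost (AB)
and XGBoost (XGB).

Evaluation follows two protocols: a stratified 80:20 independent split
and stratified 10-fold cross-validation. Standardization statistics
are always fit on the training rows of each split or fold only.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .eval_metrics import MetricsReport, evaluate_predictions
from .feature_assembly import ScalerState, apply_scaler, fit_scaler
from .seq_io import LabeledDataset

BAGGING_FAMILIES = ("RF", "ETC", "DT", "BC")
BOOSTING_FAMILIES = ("GB", "HGB", "AB", "XGB")
FAMILIES = BAGGING_FAMILIES + BOOSTING_FAMILIES

#: pinned ensemble size where the library default differs
N_ESTIMATORS = 100

DECISION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus hyperparameter overrides and seed."""

    family: str
    hyperparameters: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )

    def resolved_hyperparameters(self) -> dict:
        base = dict(_FAMILY_DEFAULTS[self.family])
        base.update(self.hyperparameters)
        return base


@dataclass(frozen=True)
class SplitSpec:
    """Evaluation protocol: independent 80:20 split or k-fold CV."""

    mode: str = "independent"
    train_fraction: float = 0.8
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("independent", "kfold"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


_FAMILY_DEFAULTS = {
    "RF": {"n_estimators": N_ESTIMATORS},
    "ETC": {"n_estimators": N_ESTIMATORS},
    "DT": {},
    "BC": {"n_estimators": N_ESTIMATORS},
    "GB": {"n_estimators": N_ESTIMATORS},
    "HGB": {},
    "AB": {"n_estimators": N_ESTIMATORS},
    "XGB": {"n_estimators": N_ESTIMATORS},
}


def make_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn / xgboost estimator for a spec."""
    hp = spec.resolved_hyperparameters()
    seed = spec.seed
    if spec.family == "RF":
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.family == "ETC":
        return ExtraTreesClassifier(random_state=seed, **hp)
    if spec.family == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.family == "BC":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            random_state=seed,
            **hp,
        )
    if spec.family == "GB":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if spec.family == "HGB":
        return HistGradientBoostingClassifier(random_state=seed, **hp)
    if spec.family == "AB":
        return AdaBoostClassifier(random_state=seed, **hp)
    if spec.family == "XGB":
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            **hp,
        )
    raise ValueError(f"unknown family {spec.family!r}")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it safely."""

    spec: ModelSpec
    estimator: object
    feature_names: tuple[str, ...]
    scaler: ScalerState | None = None

    def _check_names(self, names) -> None:
        if names is not None and tuple(names) != self.feature_names:
            raise ValueError(
                "feature names differ from those used in training"
            )

    def predict_scores(self, X: np.ndarray, names=None) -> np.ndarray:
        """Positive-class probability per row (scaler applied if held)."""
        self._check_names(names)
        if self.scaler is not None:
            X = apply_scaler(self.scaler, X)
        return self.estimator.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray, names=None) -> np.ndarray:
        return (
            self.predict_scores(X, names) >= DECISION_THRESHOLD
        ).astype(int)

    def save(self, path: str | Path) -> None:
        """Self-describing archive: JSON-style manifest + model blob."""
        payload = {
            "manifest": {
                "family": self.spec.family,
                "hyperparameters": self.spec.resolved_hyperparameters(),
                "seed": self.spec.seed,
                "feature_names": list(self.feature_names),
                "has_scaler": self.scaler is not None,
            },
            "estimator": self.estimator,
            "scaler": self.scaler,
            "spec": self.spec,
        }
        with open(path, "wb") as handle:
            pickle.dump(payload, handle)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path, "rb") as handle:
            payload = pickle.load(handle)
        return cls(
            spec=payload["spec"],
            estimator=payload["estimator"],
            feature_names=tuple(payload["manifest"]["feature_names"]),
            scaler=payload["scaler"],
        )


def _require_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")


def independent_split(
    dataset: LabeledDataset, spec: SplitSpec = SplitSpec()
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified 80:20 (by default) split of a labeled dataset."""
    y = dataset.labels
    _require_two_classes(y)
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=y if spec.stratified else None,
        random_state=spec.seed,
    )
    windows = dataset.windows
    return (
        LabeledDataset(
            [windows[i] for i in sorted(train_idx)],
            provenance=f"{dataset.provenance}[train]",
        ),
        LabeledDataset(
            [windows[i] for i in sorted(test_idx)],
            provenance=f"{dataset.provenance}[test]",
        ),
    )


def kfold_indices(
    y: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold (train_idx, test_idx) pairs."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > y.size:
        raise ValueError(f"k={k} exceeds dataset size {y.size}")
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, test) for train, test in splitter.split(np.zeros_like(y), y)
    ]


def kfold_split(
    dataset: LabeledDataset, k: int = 10, seed: int = 0
) -> list[LabeledDataset]:
    """Partition a dataset into k stratified, near-equal folds."""
    folds = kfold_indices(dataset.labels, k=k, seed=seed)
    windows = dataset.windows
    return [
        LabeledDataset(
            [windows[i] for i in sorted(test)],
            provenance=f"{dataset.provenance}[fold{f}]",
        )
        for f, (_, test) in enumerate(folds)
    ]


def train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_names=None,
    scaler: ScalerState | None = None,
) -> TrainedModel:
    """Fit one classifier; reproducible given the spec's seed.

    ``X`` is expected to be standardized already; pass ``scaler`` so
    the model can standardize future raw inputs identically.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _require_two_classes(y)
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    estimator = make_estimator(spec)
    estimator.fit(X, y)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        feature_names=tuple(feature_names),
        scaler=scaler,
    )


def evaluate(
    model: TrainedModel, X: np.ndarray, y: np.ndarray
) -> MetricsReport:
    """Acc/Sp/Sn/MCC (and AUC when both classes present) on labeled data."""
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ValueError("cannot evaluate on an empty set")
    scores = model.predict_scores(X)
    predictions = (scores >= DECISION_THRESHOLD).astype(int)
    return evaluate_predictions(y, predictions, scores)


def train_and_evaluate_split(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    split: SplitSpec = SplitSpec(),
    feature_names=None,
) -> tuple[TrainedModel, MetricsReport]:
    """Independent-split protocol on a raw (unscaled) feature matrix."""
    y = np.asarray(y, dtype=int)
    _require_two_classes(y)
    idx = np.arange(y.size)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=split.train_fraction,
        stratify=y if split.stratified else None,
        random_state=split.seed,
    )
    scaler = fit_scaler(X[train_idx], feature_names)
    model = train(
        spec,
        apply_scaler(scaler, X[train_idx]),
        y[train_idx],
        feature_names=feature_names,
        scaler=scaler,
    )
    return model, evaluate(model, X[test_idx], y[test_idx])


def cross_validate(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    feature_names=None,
) -> dict:
    """Stratified k-fold CV with per-fold scaling (no leakage).

    Returns per-fold reports plus the mean and SD of each metric.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _require_two_classes(y)
    reports: list[MetricsReport] = []
    fold_assignment = np.empty(y.size, dtype=int)
    for f, (train_idx, test_idx) in enumerate(kfold_indices(y, k, seed)):
        if test_idx.size == 0:
            raise ValueError(f"fold {f} is empty")
        fold_assignment[test_idx] = f
        scaler = fit_scaler(X[train_idx], feature_names)
        model = train(
            spec,
            apply_scaler(scaler, X[train_idx]),
            y[train_idx],
            feature_names=feature_names,
            scaler=scaler,
        )
        reports.append(evaluate(model, X[test_idx], y[test_idx]))
    summary = {}
    for key in ("acc", "sp", "sn", "mcc"):
        vals = np.array([getattr(r, key) for r in reports])
        summary[f"mean_{key}"] = float(vals.mean())
        summary[f"sd_{key}"] = float(vals.std(ddof=1))
    aucs = [r.auc for r in reports if r.auc is not None]
    if aucs:
        summary["mean_auc"] = float(np.mean(aucs))
    return {
        "folds": reports,
        "summary": summary,
        "fold_assignment": fold_assignment,
    }
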
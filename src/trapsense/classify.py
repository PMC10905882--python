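"""Genus × sex classification of target mosquitoes from spectrogram features.

The protocol mirrors a laboratory model build for a trap-mounted optical
sensor: random undersampling to a class-balanced dataset, a stratified
held-out test set, a gradient-boosted decision-tree ensemble selected by
stratified fourfold cross-validation over a small hyperparameter grid, and
event-level evaluation by one-vs-rest balanced accuracy
(BA = (Se + Sp)/2 per class, averaged without weights over the four
classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .types import TARGET_CLASSES, ClassLabel

__all__ = [
    "LabeledDataset",
    "ClassifierReport",
    "TrainedModel",
    "balance_by_undersampling",
    "split_test_set",
    "train_classifier",
    "evaluate_classifier",
    "DEFAULT_GRID",
    "mean_balanced_accuracy",
]

#: Small documented hyperparameter grid searched by cross-validation.
DEFAULT_GRID: tuple[dict, ...] = (
    {"max_depth": 3, "learning_rate": 0.1},
    {"max_depth": 3, "learning_rate": 0.3},
    {"max_depth": 6, "learning_rate": 0.1},
    {"max_depth": 6, "learning_rate": 0.3},
)
DEFAULT_N_ESTIMATORS = 150

_LABEL_INDEX = {c: i for i, c in enumerate(TARGET_CLASSES)}


@dataclass
class LabeledDataset:
    """Feature matrix with per-row class labels and assay temperatures."""

    features: np.ndarray
    labels: np.ndarray  # ClassLabel values (str), target classes only
    temperature: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, float)
        self.labels = np.asarray(self.labels)
        self.temperature = np.asarray(self.temperature, float)
        if not (len(self.features) == len(self.labels) == len(self.temperature)):
            raise ValueError("features, labels and temperature must align")
        bad = set(np.unique(self.labels)) - {c.value for c in TARGET_CLASSES}
        if bad:
            raise ValueError(f"non-target labels in dataset: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[idx], self.labels[idx], self.temperature[idx]
        )

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class ClassifierReport:
    """Test-set confusion matrix and per-class balanced accuracies (%)."""

    confusion: np.ndarray  # 4x4, rows = true class, cols = predicted
    per_class_ba: dict[str, float]
    mean_ba: float
    undefined_classes: list[str] = field(default_factory=list)


@dataclass
class TrainedModel:
    """Fitted gradient-boosting ensemble plus its CV selection record."""

    booster: XGBClassifier
    classes: tuple[ClassLabel, ...]
    cv_results: list[dict]
    best_params: dict
    fold_assignment: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class values; argmax ties resolve to the lowest index."""
        X = np.asarray(X, float)
        if isinstance(self.booster, XGBClassifier):
            proba = self.booster.predict_proba(X)
        else:  # raw Booster loaded from disk
            import xgboost

            proba = self.booster.predict(xgboost.DMatrix(X))
        idx = np.argmax(proba, axis=1)
        return np.array([self.classes[i].value for i in idx])


def balance_by_undersampling(
    data: LabeledDataset, rng_seed: int | np.random.Generator | None = None
) -> LabeledDataset:
    """Random undersampling so every class has the minority-class count."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    counts = data.class_counts()
    for c in TARGET_CLASSES:
        if counts.get(c.value, 0) < 1:
            raise ValueError(f"class {c.value} has no rows")
    n_min = min(counts.values())
    keep: list[np.ndarray] = []
    for c in TARGET_CLASSES:
        idx = np.flatnonzero(data.labels == c.value)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    idx = np.sort(np.concatenate(keep))
    return data.take(idx)


def split_test_set(
    data: LabeledDataset,
    n_test: int,
    rng_seed: int | np.random.Generator | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Set aside a stratified test set of ``n_test`` rows (n_test/4 per class)."""
    if n_test < 0 or n_test >= len(data):
        raise ValueError("n_test must be in [0, n_rows)")
    if n_test % 4 != 0:
        raise ValueError("n_test must be divisible by 4 for stratification")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    per_class = n_test // 4
    test_idx: list[np.ndarray] = []
    for c in TARGET_CLASSES:
        idx = np.flatnonzero(data.labels == c.value)
        if len(idx) < per_class:
            raise ValueError(f"class {c.value} has fewer than {per_class} rows")
        test_idx.append(rng.choice(idx, size=per_class, replace=False))
    test = np.sort(np.concatenate(test_idx)) if test_idx else np.array([], int)
    mask = np.ones(len(data), bool)
    mask[test.astype(int)] = False
    return data.take(np.flatnonzero(mask)), data.take(test.astype(int))


def _encode(labels: np.ndarray) -> np.ndarray:
    return np.array([_LABEL_INDEX[ClassLabel(v)] for v in labels])


def _ovr_ba_from_confusion(cm: np.ndarray) -> tuple[dict[str, float], list[str]]:
    """Per-class one-vs-rest BA (%) from an event-level confusion matrix."""
    per_class: dict[str, float] = {}
    undefined: list[str] = []
    total = cm.sum()
    for i, c in enumerate(TARGET_CLASSES):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            undefined.append(c.value)
            continue
        se = tp / (tp + fn)
        sp = tn / (tn + fp) if (tn + fp) > 0 else 1.0
        per_class[c.value] = 100.0 * (se + sp) / 2.0
    return per_class, undefined


def mean_balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean over classes of one-vs-rest (Se+Sp)/2, in %."""
    cm = _confusion(y_true, y_pred)
    per_class, _ = _ovr_ba_from_confusion(cm)
    return float(np.mean(list(per_class.values())))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((4, 4), dtype=int)
    for t, p in zip(_encode(y_true), _encode(y_pred)):
        cm[t, p] += 1
    return cm


def _make_booster(params: dict, seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=params.get("n_estimators", DEFAULT_N_ESTIMATORS),
        max_depth=params["max_depth"],
        learning_rate=params["learning_rate"],
        objective="multi:softprob",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def train_classifier(
    train: LabeledDataset,
    n_folds: int = 4,
    grid: Sequence[dict] = DEFAULT_GRID,
    rng_seed: int = 0,
) -> TrainedModel:
    """Fit the gradient-boosting classifier with stratified fourfold CV.

    Folds are stratified jointly by class and assay temperature (both
    structure the laboratory data); each grid point is scored by the mean
    over folds of the mean per-class balanced accuracy, and the best point
    is refit on the full training set.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if np.allclose(np.var(train.features, axis=0), 0.0):
        raise ValueError("degenerate features: zero variance everywhere")
    counts = train.class_counts()
    for c in TARGET_CLASSES:
        if counts.get(c.value, 0) < n_folds:
            raise ValueError(f"class {c.value} has fewer rows than folds")

    y = _encode(train.labels)
    strata = np.array(
        [f"{l}@{t:.0f}" for l, t in zip(train.labels, train.temperature)]
    )
    # joint class x temperature stratification; fall back to class-only when
    # some cell is smaller than the fold count
    _, strat_counts = np.unique(strata, return_counts=True)
    if strat_counts.min() < n_folds:
        strata = train.labels.astype(str)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    folds = list(skf.split(train.features, strata))
    fold_assignment = np.empty(len(train), int)
    for k, (_, val_idx) in enumerate(folds):
        fold_assignment[val_idx] = k

    cv_results = []
    for params in grid:
        scores = []
        for fit_idx, val_idx in folds:
            booster = _make_booster(params, rng_seed)
            booster.fit(train.features[fit_idx], y[fit_idx])
            proba = booster.predict_proba(train.features[val_idx])
            pred = np.array(
                [TARGET_CLASSES[i].value for i in np.argmax(proba, axis=1)]
            )
            scores.append(mean_balanced_accuracy(train.labels[val_idx], pred))
        cv_results.append({"params": dict(params), "cv_ba": float(np.mean(scores))})

    best = max(range(len(grid)), key=lambda i: cv_results[i]["cv_ba"])
    best_params = dict(grid[best])
    booster = _make_booster(best_params, rng_seed)
    booster.fit(train.features, y)
    return TrainedModel(
        booster=booster,
        classes=TARGET_CLASSES,
        cv_results=cv_results,
        best_params=best_params,
        fold_assignment=fold_assignment,
    )


def save_model(model: TrainedModel, path_prefix) -> None:
    """Persist the booster (UBJSON) plus a JSON header with the CV record."""
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    booster = (
        model.booster.get_booster()
        if isinstance(model.booster, XGBClassifier)
        else model.booster
    )
    booster.save_model(str(prefix.with_suffix(".ubj")))
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "format_version": 1,
                "classes": [c.value for c in model.classes],
                "cv_results": model.cv_results,
                "best_params": model.best_params,
            },
            fh,
            indent=2,
        )


def load_model(path_prefix) -> TrainedModel:
    import json
    from pathlib import Path

    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".json")) as fh:
        header = json.load(fh)
    import xgboost

    booster = xgboost.Booster()
    booster.load_model(str(prefix.with_suffix(".ubj")))
    return TrainedModel(
        booster=booster,
        classes=tuple(ClassLabel(c) for c in header["classes"]),
        cv_results=header["cv_results"],
        best_params=header["best_params"],
        fold_assignment=np.array([]),
    )


def evaluate_classifier(model: TrainedModel, test: LabeledDataset) -> ClassifierReport:
    """Event-level one-vs-rest evaluation on a held-out test set.

    Per class: Se = TP/(TP+FN), Sp = TN/(TN+FP) with negatives pooled over
    the other three classes; BA = (Se+Sp)/2; the headline figure is the
    unweighted mean of the four per-class BAs.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(test.features)
    cm = _confusion(test.labels, pred)
    per_class, undefined = _ovr_ba_from_confusion(cm)
    return ClassifierReport(
        confusion=cm,
        per_class_ba=per_class,
        mean_ba=float(np.mean(list(per_class.values()))),
        undefined_classes=undefined,
    )
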
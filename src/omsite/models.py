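"""Classifier registry, training, prediction and persistence.

The classifier layer holds eight ensemble models — four parallel
(bootstrap/bagging) learners and four sequential (boosting) learners —
plus five conventional baselines used for cross-comparison:

* bagging family: random forest, extremely randomized trees, a single
  decision tree trained on bootstrap-style full data, and a bagging
  meta-estimator over decision trees;
* boosting family: gradient boosting, histogram-based gradient
  boosting, AdaBoost, and XGBoost;
* conventional baselines: random forest (rf), support-vector machine
  (svm), k-nearest neighbours (knn), a single-hidden-layer feed-forward
  network (ann, 100 units), and a decision tree (dt).

Hyperparameters are the underlying library defaults, captured verbatim
into each :class:`ModelSpec` at construction so a fitted model is fully
reproducible from its spec + seed.  ``train`` fits the feature scaler
on its (raw) training table and the estimator on the scaled values;
``predict`` applies the stored scaler, so no state can leak across a
train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .feature_assembly import ScalerState, apply_scaler, fit_scaler
from .sequence_io import ValidationError

FORMAT_VERSION = "omsite-model-1"

FAMILIES = ("bagging", "boosting", "conventional")

_BUILDERS = {
    "random_forest": lambda seed: RandomForestClassifier(random_state=seed),
    "extra_trees": lambda seed: ExtraTreesClassifier(random_state=seed),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "bagging": lambda seed: BaggingClassifier(random_state=seed),
    "gradient_boost": lambda seed: GradientBoostingClassifier(random_state=seed),
    "hist_gradient_boost": lambda seed: HistGradientBoostingClassifier(
        random_state=seed
    ),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "xgboost": lambda seed: XGBClassifier(random_state=seed, n_jobs=1),
    "rf": lambda seed: RandomForestClassifier(random_state=seed),
    "svm": lambda seed: SVC(probability=True, random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "ann": lambda seed: MLPClassifier(
        hidden_layer_sizes=(100,), max_iter=500, random_state=seed
    ),
    "dt": lambda seed: DecisionTreeClassifier(random_state=seed),
}

_FAMILY_OF = {
    "random_forest": "bagging",
    "extra_trees": "bagging",
    "decision_tree": "bagging",
    "bagging": "bagging",
    "gradient_boost": "boosting",
    "hist_gradient_boost": "boosting",
    "adaboost": "boosting",
    "xgboost": "boosting",
    "rf": "conventional",
    "svm": "conventional",
    "knn": "conventional",
    "ann": "conventional",
    "dt": "conventional",
}

_REGISTRY_ORDER = (
    "random_forest",
    "extra_trees",
    "decision_tree",
    "bagging",
    "gradient_boost",
    "hist_gradient_boost",
    "adaboost",
    "xgboost",
    "rf",
    "svm",
    "knn",
    "ann",
    "dt",
)


def _jsonable_params(estimator) -> dict:
    params = {}
    for key, value in estimator.get_params(deep=False).items():
        if isinstance(value, (int, float, str, bool, type(None), tuple, list)):
            params[key] = list(value) if isinstance(value, tuple) else value
    return params


@dataclass(frozen=True)
class ModelSpec:
    """Name, family, recorded hyperparameters and seed of one classifier."""

    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.name not in _BUILDERS:
            raise ValidationError(f"unknown model name {self.name!r}")
        if self.family != _FAMILY_OF[self.name]:
            raise ValidationError(
                f"model {self.name!r} belongs to family {_FAMILY_OF[self.name]!r}, "
                f"not {self.family!r}"
            )


def make_spec(name: str, seed: int = 1, **overrides) -> ModelSpec:
    """A ModelSpec with the ecosystem defaults recorded (optionally overridden)."""
    if name not in _BUILDERS:
        raise ValidationError(
            f"unknown model name {name!r}; choose from {', '.join(_REGISTRY_ORDER)}"
        )
    estimator = _BUILDERS[name](seed)
    if overrides:
        estimator.set_params(**overrides)
    return ModelSpec(
        name=name,
        family=_FAMILY_OF[name],
        hyperparameters=_jsonable_params(estimator),
        seed=seed,
    )


def registry(seed: int = 1) -> list[ModelSpec]:
    """All 13 specs: 4 bagging + 4 boosting ensembles, then 5 baselines."""
    return [make_spec(name, seed=seed) for name in _REGISTRY_ORDER]


def _build_estimator(spec: ModelSpec):
    estimator = _BUILDERS[spec.name](spec.seed)
    known = estimator.get_params(deep=False)
    overrides = {
        k: (tuple(v) if isinstance(known.get(k), tuple) and isinstance(v, list) else v)
        for k, v in spec.hyperparameters.items()
        if k in known
    }
    estimator.set_params(**overrides)
    return estimator


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its spec, scaler and column names.

    ``center_base`` records which nucleotide-specific dataset (A/C/G/U
    center) the model was trained on, when known; prediction tooling
    uses it to dispatch or skip windows.
    """

    spec: ModelSpec
    estimator: object
    scaler: ScalerState
    feature_names: list[str]
    center_base: Optional[str] = None

    def _check_columns(self, table: pd.DataFrame) -> None:
        if list(table.columns) != self.feature_names:
            raise ValidationError(
                "feature columns do not match the columns this model was trained on"
            )


def train(
    table: pd.DataFrame, labels, spec: ModelSpec, center_base: Optional[str] = None
) -> TrainedModel:
    """Fit scaler and classifier on a raw training table.

    Requires at least two rows of each class; deterministic for a fixed
    (data, spec, seed) triple.
    """
    y = np.asarray(labels, dtype=int)
    if table.shape[0] != y.shape[0]:
        raise ValidationError("table and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    if counts.min() < 2:
        raise ValidationError("need at least 2 rows per class")
    scaler = fit_scaler(table)
    scaled = apply_scaler(table, scaler)
    estimator = _build_estimator(spec)
    estimator.fit(scaled.to_numpy(), y)
    return TrainedModel(
        spec=spec,
        estimator=estimator,
        scaler=scaler,
        feature_names=list(table.columns),
        center_base=center_base,
    )


def predict(
    model: TrainedModel, table: pd.DataFrame, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row positive-class score in [0, 1] and hard call (score >= 0.5)."""
    model._check_columns(table)
    scaled = apply_scaler(table, model.scaler)
    scores = model.estimator.predict_proba(scaled.to_numpy())[:, 1]
    scores = np.clip(scores, 0.0, 1.0)
    return scores, (scores >= threshold).astype(int)


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist spec, scaler and fitted state as one archive."""
    payload = {
        "format": FORMAT_VERSION,
        "spec": {
            "name": model.spec.name,
            "family": model.spec.family,
            "hyperparameters": model.spec.hyperparameters,
            "seed": model.spec.seed,
        },
        "scaler": {
            "mean": model.scaler.mean.tolist(),
            "std": model.scaler.std.tolist(),
            "fitted_on": model.scaler.fitted_on,
        },
        "feature_names": model.feature_names,
        "center_base": model.center_base,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model archive; refuses files from other format versions."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such model file: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupted archive
        raise IOError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != FORMAT_VERSION:
        raise ValidationError(
            f"model file {path} has format "
            f"{payload.get('format') if isinstance(payload, dict) else '<unknown>'!r}, "
            f"expected {FORMAT_VERSION!r}"
        )
    spec = ModelSpec(**payload["spec"])
    scaler = ScalerState(
        mean=np.asarray(payload["scaler"]["mean"], dtype=float),
        std=np.asarray(payload["scaler"]["std"], dtype=float),
        fitted_on=int(payload["scaler"]["fitted_on"]),
    )
    return TrainedModel(
        spec=spec,
        estimator=payload["estimator"],
        scaler=scaler,
        feature_names=list(payload["feature_names"]),
        center_base=payload.get("center_base"),
    )
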
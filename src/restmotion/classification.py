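"""The four benchmark classifiers behind one train/predict contract.

Hyperparameters are fixed to the study configuration: KNN with k=3,
SVM with a polynomial kernel, random forest with 120 trees, Gaussian
naive Bayes.  Everything else uses widely accepted defaults and is
overridable through ``ClassifierSpec.params``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ConfigurationError, DataError, FitError, SchemaError
from .features import feature_columns

KINDS = ("KNN", "SVM", "RF", "NB")

_DEFAULT_PARAMS: dict[str, dict] = {
    "KNN": {"k": 3},
    "SVM": {"kernel": "polynomial", "degree": 3, "cost": 1.0},
    "RF": {"n_trees": 120},
    "NB": {"distribution": "normal"},
}


@dataclass
class ClassifierSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = self.kind.upper()
        if self.kind not in KINDS:
            raise ConfigurationError(f"kind must be one of {KINDS}, got {self.kind!r}")
        merged = dict(_DEFAULT_PARAMS[self.kind])
        merged.update(self.params)
        self.params = merged


@dataclass
class Prediction:
    subject_id: str
    predicted: str
    actual: str


@dataclass
class FittedModel:
    spec: ClassifierSpec
    estimator: object
    columns: list[str]


def _build_estimator(spec: ClassifierSpec, n_features: int):
    p = spec.params
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=p["k"], metric="euclidean")
    if spec.kind == "SVM":
        if p["kernel"] != "polynomial":
            raise ConfigurationError("only the polynomial SVM kernel is supported")
        # gamma = 1 / n_features, no data-variance scaling
        return SVC(kernel="poly", degree=p["degree"], C=p["cost"], gamma="auto")
    if spec.kind == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_trees"],
            max_features="sqrt",
            random_state=spec.seed,
        )
    return GaussianNB()


def train(spec: ClassifierSpec, table: pd.DataFrame) -> FittedModel:
    """Fit one classifier on a normalized feature table."""
    cols = feature_columns(table)
    x = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    if x.size == 0:
        raise DataError("empty training table")
    if np.isnan(x).any():
        raise DataError("training table contains missing values")
    if np.unique(y).size < 2:
        raise FitError("training table contains a single class")
    if spec.kind == "KNN" and spec.params["k"] > len(y) - 1:
        raise FitError(
            f"KNN k={spec.params['k']} exceeds n-1={len(y) - 1} training rows"
        )
    est = _build_estimator(spec, n_features=x.shape[1])
    est.fit(x, y)
    return FittedModel(spec=spec, estimator=est, columns=cols)


def predict(model: FittedModel, table: pd.DataFrame) -> list[Prediction]:
    """One prediction per row; columns must match training exactly."""
    cols = feature_columns(table)
    if cols != model.columns:
        raise SchemaError(
            f"feature columns differ from training: got {len(cols)}, "
            f"expected {len(model.columns)}"
        )
    if table.shape[0] == 0:
        return []
    x = table[cols].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise DataError("prediction table contains missing values")
    yhat = model.estimator.predict(x)
    ids = (
        table["subject_id"].tolist()
        if "subject_id" in table.columns
        else [str(i) for i in range(len(yhat))]
    )
    actual = (
        table["label"].tolist() if "label" in table.columns else [""] * len(yhat)
    )
    return [
        Prediction(subject_id=s, predicted=str(p), actual=str(a))
        for s, p, a in zip(ids, yhat, actual)
    ]
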
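"""Classical machine-learning baselines for immunogenicity prediction.

Five standard classifiers -- logistic regression, an RBF-kernel SVM,
gradient-boosted trees (XGBoost), a random forest and extremely randomized
trees -- trained on exactly the information the convolutional model sees:
the flattened one-hot peptide and MHC matrices concatenated with the scaled
binding-affinity and TAP scalars.  Hyperparameters default to the tuned
values of the reference study (10-fold CV-selected); any can be overridden.

Class weighting uses the same w_c = (1/S_c)(T/2) scheme as the network,
applied as per-sample weights (default on, for parity; togglable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import binary_metrics, class_weights

BASELINE_KINDS = (
    "logistic-regression",
    "support-vector-machine",
    "gradient-boosted-trees",
    "random-forest",
    "extremely-randomized-trees",
)

#: Tuned hyperparameters per model kind.
DEFAULT_HYPERPARAMETERS = {
    "logistic-regression": {"penalty": "l2", "C": 2.21},
    "support-vector-machine": {"kernel": "rbf", "gamma": 0.1, "C": 10},
    "gradient-boosted-trees": {
        "max_depth": 10, "min_child_weight": 1.0, "gamma": 1.625,
        "subsample": 1.0, "colsample_bytree": 1.0,
    },
    "random-forest": {"n_estimators": 200, "min_samples_leaf": 2},
    "extremely-randomized-trees": {"n_estimators": 1000, "min_samples_leaf": 2},
}


class BaselineConfigError(ValueError):
    """Unrecognized baseline kind or invalid hyperparameters."""


class NotTrainedError(RuntimeError):
    """Operation requires a fitted model."""


@dataclass
class BaselineSpec:
    """A baseline model kind plus its hyperparameters (tuned defaults)."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    use_class_weights: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in BASELINE_KINDS:
            raise BaselineConfigError(
                f"unknown baseline kind {self.kind!r}; choose from {BASELINE_KINDS}"
            )
        merged = dict(DEFAULT_HYPERPARAMETERS[self.kind])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged


def build_baseline(spec: BaselineSpec):
    """Instantiate an untrained scikit-learn / xgboost classifier."""
    hp = spec.hyperparameters
    if spec.kind == "logistic-regression":
        return LogisticRegression(max_iter=5000, random_state=spec.seed, **hp)
    if spec.kind == "support-vector-machine":
        return SVC(random_state=spec.seed, **hp)
    if spec.kind == "gradient-boosted-trees":
        return XGBClassifier(random_state=spec.seed, n_jobs=1,
                             eval_metric="logloss", **hp)
    if spec.kind == "random-forest":
        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if spec.kind == "extremely-randomized-trees":
        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **hp)
    raise BaselineConfigError(f"unknown baseline kind {spec.kind!r}")


class TrainedBaseline:
    """A fitted baseline with a uniform score interface.

    ``scores`` returns a continuous score per sample: predicted positive
    probability where the estimator exposes one, otherwise (SVM) the
    decision-function value; ``predicted_positive`` uses probability > 0.5
    or decision function > 0 respectively.
    """

    def __init__(self, spec: BaselineSpec, estimator):
        self.spec = spec
        self.estimator = estimator

    def scores(self, x: np.ndarray) -> np.ndarray:
        if hasattr(self.estimator, "predict_proba"):
            return self.estimator.predict_proba(x)[:, 1]
        return self.estimator.decision_function(x)

    def predicted_positive(self, x: np.ndarray) -> np.ndarray:
        if hasattr(self.estimator, "predict_proba"):
            return self.scores(x) > 0.5
        return self.estimator.decision_function(x) > 0.0


def train_baseline(spec: BaselineSpec, x: np.ndarray, y: np.ndarray
                   ) -> TrainedBaseline:
    """Fit one baseline, with per-sample class weights unless disabled."""
    est = build_baseline(spec)
    y = np.asarray(y, dtype=int)
    if spec.use_class_weights:
        cw = class_weights(int(y.sum()), int((y == 0).sum()))
        est.fit(x, y, sample_weight=cw.per_sample(y))
    else:
        est.fit(x, y)
    return TrainedBaseline(spec, est)


def compare_models(models: dict[str, object], x_test: np.ndarray,
                   y_test: np.ndarray) -> pd.DataFrame:
    """Accuracy/precision/recall table for trained models on one test set.

    ``models`` maps display names to objects exposing ``predicted_positive``
    (TrainedBaseline, or any adapter with the same method).
    """
    rows = []
    for name, model in models.items():
        if not hasattr(model, "predicted_positive"):
            raise NotTrainedError(f"model {name!r} lacks a predicted_positive method")
        pred = np.asarray(model.predicted_positive(x_test), dtype=bool)
        acc, prec, rec = binary_metrics(pred, y_test)
        rows.append({"model": name, "accuracy": acc,
                     "precision": np.nan if prec is None else prec,
                     "recall": np.nan if rec is None else rec})
    return pd.DataFrame(rows)


class CNNAdapter:
    """Expose a trained convolutional model through the comparison interface.

    The adapter carries its own encoded test arrays (aligned row-for-row
    with the flattened matrix handed to :func:`compare_models`) because the
    network consumes structured matrices rather than flat vectors.
    """

    def __init__(self, trained, test_arrays: dict):
        self.trained = trained
        self.test_arrays = test_arrays

    def predicted_positive(self, _x_ignored=None) -> np.ndarray:
        from .cnn import predict
        return predict(self.trained, self.test_arrays) > 0.5
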
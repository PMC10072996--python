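"""The two classifier families and their introspection utilities.

The baseline discriminators are a random forest (30 000 trees, minimum
sample split 5, balanced class weights — the forest size is configurable
and is run scaled down for desk-scale work) and an L1-penalised logistic
regression (C = 0.1, tolerance 0.01, saga solver, balanced class weights).
The second-stage constitutive-vs-cryptic model reuses the logistic
configuration with C = 0.0018.  Balanced class weighting compensates the
30:1 negative excess in training data.

Feature importances are impurity importances for the forest (non-negative,
summing to 1) and signed coefficients for the logistic model; "top"
features are ranked by coefficient magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from cpascan.features import BinGrid, FeatureMatrix, feature_name
from cpascan.motifs import MotifRegistry

MODEL_FORMAT_VERSION = 1

BASELINE_LR_C = 0.1
CRYPTIC_LR_C = 0.0018


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of one classifier.

    Exactly one learner is active.  ``n_trees`` defaults to the full-scale
    30 000; pass a smaller value (e.g. 300) for desk-scale runs.
    """

    learner: str  # "forest" | "linear"
    n_trees: int = 30_000
    min_samples_split: int = 5
    penalty: str = "l1"
    C: float = BASELINE_LR_C
    tol: float = 0.01
    solver: str = "saga"
    class_weight: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in ("forest", "linear"):
            raise ModelError(f"unknown learner {self.learner!r}")
        if self.C <= 0:
            raise ModelError("regularization strength C must be positive")
        if self.n_trees < 1:
            raise ModelError("n_trees must be >= 1")

    @classmethod
    def forest(cls, n_trees: int = 30_000, seed: int = 0, **kw) -> "ModelConfig":
        return cls(learner="forest", n_trees=n_trees, seed=seed, **kw)

    @classmethod
    def linear(cls, C: float = BASELINE_LR_C, seed: int = 0, **kw) -> "ModelConfig":
        return cls(learner="linear", C=C, seed=seed, **kw)

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


@dataclass
class TrainedModel:
    """A fitted classifier bound to its training feature columns."""

    config: ModelConfig
    estimator: object
    feature_names_: list[str]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names_):
            raise ModelError(
                f"expected {len(self.feature_names_)} features, got {X.shape[1]}"
            )
        classes = list(self.estimator.classes_)
        return self.estimator.predict_proba(X)[:, classes.index(1)]

    @property
    def feature_importances(self) -> dict[str, float]:
        """Feature name -> importance (forest: impurity importance; linear:
        signed coefficient)."""
        if self.config.learner == "forest":
            values = self.estimator.feature_importances_
        else:
            values = self.estimator[-1].coef_[0]
        return dict(zip(self.feature_names_, values))

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format_version": MODEL_FORMAT_VERSION,
                "config": self.config,
                "feature_names": self.feature_names_,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(
        cls, path: str | Path, expected_feature_names: Sequence[str] | None = None
    ) -> "TrainedModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ModelError(
                f"unsupported model archive version {payload.get('format_version')}"
            )
        names = payload["feature_names"]
        if expected_feature_names is not None and list(expected_feature_names) != list(
            names
        ):
            raise ModelError("feature names in archive do not match expectation")
        return cls(payload["config"], payload["estimator"], list(names))


def _binary_labels(labels: np.ndarray, positive_label) -> np.ndarray:
    y = (np.asarray(labels) == positive_label).astype(int)
    if len(np.unique(y)) < 2:
        raise ModelError(
            "training data must contain both classes "
            f"(positive label {positive_label!r})"
        )
    return y


def train(
    config: ModelConfig,
    matrix: FeatureMatrix,
    positive_label="positive",
) -> TrainedModel:
    """Fit the configured learner on a feature matrix.

    Deterministic for a given seed.  Raises on single-class input.
    """
    y = _binary_labels(matrix.labels, positive_label)
    if config.learner == "forest":
        est = RandomForestClassifier(
            n_estimators=config.n_trees,
            min_samples_split=config.min_samples_split,
            class_weight=config.class_weight,
            random_state=config.seed,
            n_jobs=1,
        )
    else:
        # features are standardized for the logistic family only: the raw
        # linear-domain odds span ~10 orders of magnitude, which leaves the
        # L1/saga problem badly conditioned; the forest is scale-invariant
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "lr",
                    LogisticRegression(
                        l1_ratio=1.0 if config.penalty == "l1" else 0.0,
                        C=config.C,
                        tol=config.tol,
                        solver=config.solver,
                        class_weight=config.class_weight,
                        random_state=config.seed,
                        max_iter=2000,
                    ),
                ),
            ]
        )
    est.fit(matrix.values, y)
    return TrainedModel(config, est, list(matrix.feature_names_))


def top_k_features(lr_model: TrainedModel, k: int = 10) -> list[str]:
    """The k features with largest-magnitude coefficients of a linear model.

    Ties break by feature-name order.  If fewer than ``k`` coefficients are
    nonzero, all nonzero ones are returned with a warning.
    """
    if lr_model.config.learner != "linear":
        raise ModelError("top_k_features requires a linear model")
    coefs = lr_model.feature_importances
    nonzero = [(name, c) for name, c in coefs.items() if c != 0.0]
    if len(nonzero) < k:
        warnings.warn(
            f"only {len(nonzero)} nonzero coefficients available for top-{k}",
            stacklevel=2,
        )
    ranked = sorted(nonzero, key=lambda nc: (-abs(nc[1]), nc[0]))
    return [name for name, _ in ranked[:k]]


def collapse_pas_dse(
    matrix: FeatureMatrix,
    pas_features: Sequence[str],
    dse_features: Sequence[str],
) -> FeatureMatrix:
    """Collapse the matrix onto two columns: per-row maxima over the named
    PAS feature cells and over the named DSE feature cells."""
    name_to_col = {n: i for i, n in enumerate(matrix.feature_names_)}
    for group, names in (("PAS", pas_features), ("DSE", dse_features)):
        unknown = [n for n in names if n not in name_to_col]
        if unknown:
            raise ModelError(f"unknown {group} feature name(s): {unknown}")
        if not names:
            raise ModelError(f"{group} feature set must be non-empty")
    pas_idx = [name_to_col[n] for n in pas_features]
    dse_idx = [name_to_col[n] for n in dse_features]
    values = np.column_stack(
        [
            matrix.values[:, pas_idx].max(axis=1),
            matrix.values[:, dse_idx].max(axis=1),
        ]
    )
    return FeatureMatrix(values, ["PAS", "DSE"], matrix.labels, matrix.example_ids)


def importance_heatmap(
    model: TrainedModel,
    grid: BinGrid,
    registry: MotifRegistry,
    normalize_rows: bool = False,
) -> pd.DataFrame:
    """Reshape importances/coefficients into a representation x bin matrix.

    With ``normalize_rows`` each row is divided by its maximum absolute
    value (rows of all zeros are left untouched).
    """
    expected = [
        feature_name(rep_id, grid, i)
        for rep_id in registry.ids
        for i in range(grid.n_bins)
    ]
    if expected != model.feature_names_:
        raise ModelError("model was not trained on this registry x grid layout")
    imp = model.feature_importances
    values = np.array([imp[n] for n in expected]).reshape(
        len(registry), grid.n_bins
    )
    if normalize_rows:
        scale = np.abs(values).max(axis=1, keepdims=True)
        scale[scale == 0] = 1.0
        values = values / scale
    return pd.DataFrame(values, index=registry.ids, columns=range(grid.n_bins))
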
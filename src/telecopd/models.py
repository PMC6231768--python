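"""Uniform train / predict / tune contract over the benchmarked model
families.

Three families share one interface:

* ``elasticnet`` — logistic regression with an *adaptive* elastic-net
  penalty: a univariate-association filter (point-biserial correlation of
  each standardized feature with the label, computed on the training data
  only) rescales each feature so that weakly associated features carry a
  proportionally heavier penalty. Implemented by feature rescaling in
  front of scikit-learn's saga elastic-net solver.
* ``svm`` — a kernelized sparse maximum-margin classifier (RBF support
  vector machine); scores are signed margins.
* ``boosted`` — a gradient-boosted tree ensemble
  (:class:`~sklearn.ensemble.HistGradientBoostingClassifier`), well suited
  to the heavily imbalanced episode data.

A fourth, recurrent-network family is acknowledged as an optional plug-in
slot behind the same contract but is not implemented here.

Class imbalance is handled by inverse-prevalence instance weighting
(enabled by default). Standardization statistics and the association
filter are always computed on the training data handed to :func:`fit`, so
nested cross-validation stays leak-free as long as the caller passes
training folds only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from ._rng import substream

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "FittedModel",
    "default_specs",
    "fit",
    "predict_scores",
    "tune",
    "save_model",
    "load_model",
]

SERIAL_VERSION = 1

FAMILIES = ("elasticnet", "svm", "boosted", "recurrent")

# Grids favour strongly regularized settings: episode data are heavily
# imbalanced (tens of events against tens of thousands of episodes), where
# shallow, damped learners generalize far better than deep ones.
_DEFAULT_GRIDS = {
    "elasticnet": {"C": [0.03, 0.3, 3.0], "l1_ratio": [0.2, 0.8]},
    "svm": {"C": [0.3, 3.0], "gamma": ["scale"]},
    "boosted": {"learning_rate": [0.05, 0.1], "max_leaf_nodes": [7, 15],
                "max_iter": [100], "min_samples_leaf": [100],
                "l2_regularization": [1.0, 10.0], "max_features": [0.4, 1.0]},
}


class DegenerateFitError(ValueError):
    """Training labels contain a single class; no classifier can be fitted."""


@dataclass
class ModelSpec:
    """Declarative description of one model family and its search space."""

    family: str
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    search: str = "grid"            # "grid" | "random"
    budget: int = 10                # candidates evaluated in random mode
    imbalance_weighting: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; known: {FAMILIES}")
        if self.search not in ("grid", "random"):
            raise ValueError(f"search must be 'grid' or 'random', got {self.search!r}")
        if self.budget < 1:
            raise ValueError(f"budget must be >= 1, got {self.budget}")
        if not self.grid:
            self.grid = dict(_DEFAULT_GRIDS.get(self.family, {}))

    def candidates(self) -> list[dict]:
        """The hyperparameter points the search will evaluate, in order.

        Grid mode enumerates the full product; random mode samples
        ``budget`` points (with replacement) from a stream derived from
        (seed, family) so different families draw independent,
        reproducible sequences.
        """
        if not self.grid:
            raise ValueError("empty hyperparameter search space")
        names = sorted(self.grid)
        if self.search == "grid":
            return [dict(zip(names, combo))
                    for combo in itertools.product(*(self.grid[n] for n in names))]
        rng = substream(self.seed, "models", FAMILIES.index(self.family))
        out = []
        for _ in range(self.budget):
            out.append({n: self.grid[n][rng.integers(len(self.grid[n]))]
                        for n in names})
        return out


def default_specs(seed: int = 0) -> dict[str, ModelSpec]:
    """The benchmark's default model grid (one spec per implemented family)."""
    return {
        "elasticnet": ModelSpec("elasticnet", search="grid", seed=seed),
        "svm": ModelSpec("svm", search="grid", seed=seed),
        "boosted": ModelSpec("boosted", search="random", budget=4, seed=seed),
    }


@dataclass
class FittedModel:
    family: str
    params: dict
    feature_names: list
    center: np.ndarray          # training-fold means
    scale: np.ndarray           # training-fold SDs (1 where constant)
    assoc_scale: np.ndarray     # adaptive-penalty rescaling (1 for trees)
    estimator: object

    def _transform(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise ValueError(
                "feature manifest mismatch: model was fitted on "
                f"{len(self.feature_names)} named features; input differs")
        Z = (X.to_numpy(dtype=float) - self.center) / self.scale
        return Z * self.assoc_scale


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return center, scale


def _association(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|point-biserial correlation| of each standardized column with y."""
    yc = y - y.mean()
    denom = np.sqrt((yc ** 2).sum()) * np.sqrt((Z ** 2).sum(axis=0))
    denom[denom == 0] = 1.0
    return np.abs(yc @ Z) / denom


def fit(X: pd.DataFrame, y, spec: ModelSpec, params: dict | None = None) -> FittedModel:
    """Fit one model family with fixed hyperparameters.

    ``params`` defaults to the first point of the spec's candidate list.
    All preprocessing statistics come from (X, y) only.
    """
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateFitError(f"labels contain a single class {classes}")
    if spec.family == "recurrent":
        raise NotImplementedError(
            "the recurrent-network family is an optional plug-in and is not "
            "implemented in this package")
    params = dict(params if params is not None else spec.candidates()[0])

    Xv = X.to_numpy(dtype=float)
    center, scale = _standardize_stats(Xv)
    Z = (Xv - center) / scale

    assoc_scale = np.ones(Z.shape[1])
    if spec.family == "elasticnet":
        # heavier penalty on weakly associated features, via rescaling
        assoc_scale = _association(Z, y) + 0.05
        assoc_scale = assoc_scale / assoc_scale.mean()
    Zs = Z * assoc_scale

    sample_weight = None
    if spec.imbalance_weighting:
        prev = y.mean()
        sample_weight = np.where(y == 1, 0.5 / max(prev, 1e-12),
                                 0.5 / max(1 - prev, 1e-12))

    if spec.family == "elasticnet":
        est = LogisticRegression(
            solver="saga", max_iter=300, tol=1e-3,
            C=float(params.get("C", 1.0)),
            l1_ratio=float(params.get("l1_ratio", 0.5)),
            random_state=spec.seed)
        est.fit(Zs, y, sample_weight=sample_weight)
    elif spec.family == "svm":
        est = SVC(kernel="rbf", C=float(params.get("C", 1.0)),
                  gamma=params.get("gamma", "scale"), random_state=spec.seed)
        est.fit(Zs, y, sample_weight=sample_weight)
    elif spec.family == "boosted":
        est = HistGradientBoostingClassifier(
            learning_rate=float(params.get("learning_rate", 0.05)),
            max_iter=int(params.get("max_iter", 100)),
            max_leaf_nodes=int(params.get("max_leaf_nodes", 7)),
            min_samples_leaf=min(int(params.get("min_samples_leaf", 100)),
                                 max(1, len(y) // 5)),
            l2_regularization=float(params.get("l2_regularization", 10.0)),
            max_features=float(params.get("max_features", 1.0)),
            early_stopping=False, random_state=spec.seed)
        est.fit(Zs, y, sample_weight=sample_weight)
    return FittedModel(spec.family, params, list(X.columns), center, scale,
                       assoc_scale, est)


def predict_scores(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Real-valued risk scores (higher = higher predicted risk).

    Scores are only meaningful up to monotone rescaling; downstream
    evaluation uses rank statistics (AUC), which such rescaling cannot
    change.
    """
    Z = model._transform(X)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return est.predict_proba(Z)[:, 1]
    return est.decision_function(Z)


def save_model(model: FittedModel, path) -> None:
    """Serialize a fitted model with its feature manifest and a format
    version, so stale artifacts are rejected on load."""
    import joblib

    joblib.dump({"serial_version": SERIAL_VERSION,
                 "family": model.family,
                 "params": model.params,
                 "feature_names": model.feature_names,
                 "model": model}, path)


def load_model(path) -> FittedModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("serial_version") != SERIAL_VERSION:
        raise ValueError(
            f"unsupported model file version {payload.get('serial_version')}; "
            f"this package reads version {SERIAL_VERSION}")
    return payload["model"]


def tune(X: pd.DataFrame, y, groups, inner_folds, spec: ModelSpec,
         ) -> tuple[dict, pd.DataFrame]:
    """Select hyperparameters by merged inner-validation AUC.

    ``inner_folds`` is a sequence of (train_indices, val_indices) pairs,
    patient-disjoint within each pair (checked; a shared patient raises).
    Every candidate is fitted on each inner-training split and scored on
    the merged inner-validation predictions; the argmax is returned along
    with the per-candidate AUC table. Ties go to the earlier candidate.
    """
    from .evaluation import auc  # local import to avoid a cycle

    y = np.asarray(y, dtype=int)
    groups = np.asarray(groups)
    for tr, va in inner_folds:
        shared = set(groups[tr]) & set(groups[va])
        if shared:
            raise ValueError(
                f"patient leakage: ids {sorted(shared)[:5]} appear in both an "
                "inner-training and its inner-validation fold")
    candidates = spec.candidates()
    rows = []
    best, best_auc = None, -np.inf
    for i, params in enumerate(candidates):
        scores, labels = [], []
        for tr, va in inner_folds:
            m = fit(X.iloc[tr], y[tr], spec, params)
            scores.append(predict_scores(m, X.iloc[va]))
            labels.append(y[va])
        merged_auc = auc(np.concatenate(scores), np.concatenate(labels))
        rows.append({"candidate": i, **params, "inner_auc": merged_auc})
        if merged_auc > best_auc:
            best, best_auc = params, merged_auc
    return best, pd.DataFrame(rows)
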
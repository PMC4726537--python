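"""Bootstrap-aggregated regression forests with a statsmodels-style API.

The model object :class:`RandomForest` is built from a response vector and a
design matrix; :meth:`RandomForest.fit` grows the ensemble and returns a
:class:`RandomForestResults` carrying the trees, out-of-bag bookkeeping,
prediction and evaluation methods and a text ``summary()``.

Each tree is grown on an independent bootstrap resample (size n, drawn with
replacement) and the ensemble prediction is the plain arithmetic mean over
trees.  Accuracy is reported as the mean absolute error together with the
Pearson correlation between predicted and observed values, the two measures
used throughout this package.

Per-tree random streams are derived from the forest seed with
``np.random.SeedSequence([seed, tree_index])``, a counter scheme under which
growing more trees never reshuffles the earlier ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import _cart
from .tree import RegressionTree, TreeConfig, grow_tree

__all__ = [
    "ForestConfig",
    "EvalMetrics",
    "RandomForest",
    "RandomForestResults",
    "fit_forest",
    "predict",
    "evaluate",
    "save_forest",
    "load_forest",
    "format_p_value",
]

#: p-values smaller than this are displayed as "< 1e-300" instead of 0.
P_FLOOR = 1e-300


@dataclass
class ForestConfig:
    """Ensemble hyper-parameters.

    Defaults mirror common regression-forest practice: 100 trees, a third of
    the features tried at each split (rounded up), leaves of at least 5
    records, and bootstrap resampling switched on.
    """

    n_trees: int = 100
    mtry: Optional[int] = None  # None -> ceil(n_features / 3)
    min_leaf: int = 5
    max_depth: Optional[int] = None
    bootstrap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry is None:
            return max(1, math.ceil(n_features / 3))
        if self.mtry > n_features:
            raise ValueError(
                f"mtry={self.mtry} exceeds the {n_features} available features"
            )
        return self.mtry


@dataclass
class EvalMetrics:
    """Prediction accuracy on a (predicted, observed) pair set.

    ``pearson_r`` and ``p_value`` are NaN, with ``correlation_defined``
    False, when either side has zero variance (the correlation is undefined,
    and is reported as such rather than silently propagated).
    """

    mae: float
    pearson_r: float
    p_value: float
    n: int
    correlation_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "p_value_display": format_p_value(self.p_value)
            if self.correlation_defined
            else "undefined",
            "n": self.n,
            "correlation_defined": self.correlation_defined,
        }


def format_p_value(p: float) -> str:
    """Display helper: sub-representable p-values print as '< 1e-300'."""
    if np.isnan(p):
        return "undefined"
    if p < P_FLOOR:
        return "< 1e-300"
    return f"{p:.3g}"


def evaluate_pairs(y_pred: np.ndarray, y_true: np.ndarray) -> EvalMetrics:
    """MAE and Pearson r (two-sided t-transform p-value) for paired values."""
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_pred.shape != y_true.shape:
        raise ValueError("prediction and observation vectors differ in length")
    n = y_pred.size
    if n == 0:
        raise ValueError("empty evaluation set")
    mae = float(np.mean(np.abs(y_pred - y_true)))
    if n < 3 or np.ptp(y_pred) == 0.0 or np.ptp(y_true) == 0.0:
        return EvalMetrics(mae, float("nan"), float("nan"), n, False)
    r, p = stats.pearsonr(y_pred, y_true)
    return EvalMetrics(mae, float(r), float(p), n, True)


class RandomForest:
    """Regression-forest model for a response and design matrix.

    Parameters
    ----------
    endog : (n,) array
        Response vector (e.g. serum PTH in pg/mL).
    exog : (n, f) array
        Feature matrix; columns are named by ``feature_names``.
    feature_names : sequence of str, optional
    config : ForestConfig, optional
    """

    def __init__(self, endog, exog, feature_names=None, config: Optional[ForestConfig] = None):
        self.endog = np.ascontiguousarray(endog, dtype=np.float64)
        self.exog = np.ascontiguousarray(np.atleast_2d(exog), dtype=np.float64)
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog must have the same number of records")
        if self.endog.shape[0] < 2:
            raise ValueError("need at least 2 records to fit a forest")
        if np.isnan(self.exog).any() or np.isnan(self.endog).any():
            raise ValueError("missing values in the design; filter complete cases first")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(self.exog.shape[1])]
        if len(feature_names) != self.exog.shape[1]:
            raise ValueError("feature_names length does not match exog columns")
        self.feature_names = list(feature_names)
        self.config = config or ForestConfig()

    @classmethod
    def from_feature_matrix(cls, matrix, config: Optional[ForestConfig] = None,
                            train_idx=None) -> "RandomForest":
        """Build the model from a :class:`~mbdforest.dataset.FeatureMatrix`,
        optionally restricted to training indices."""
        X, y = matrix.X, matrix.y
        if train_idx is not None:
            X, y = X[train_idx], y[train_idx]
        return cls(y, X, feature_names=matrix.feature_names, config=config)

    def fit(self, seed: Optional[int] = None) -> "RandomForestResults":
        """Grow the ensemble; returns the fitted results object."""
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        n, f = self.exog.shape
        mtry = cfg.resolve_mtry(f)
        tcfg = TreeConfig(mtry=mtry, min_leaf=cfg.min_leaf, max_depth=cfg.max_depth)
        trees: list[RegressionTree] = []
        oob: list[np.ndarray] = []
        all_idx = np.arange(n, dtype=np.int64)
        for t in range(cfg.n_trees):
            rng = np.random.default_rng(np.random.SeedSequence([seed, t]))
            if cfg.bootstrap:
                sample = rng.integers(0, n, size=n).astype(np.int64)
                oob.append(np.setdiff1d(all_idx, sample))
            else:
                sample = all_idx
                oob.append(np.empty(0, dtype=np.int64))
            trees.append(grow_tree(self.exog, self.endog, tcfg, rng, sample_idx=sample))
        return RandomForestResults(self, trees, oob, seed)


class RandomForestResults:
    """A fitted forest: trees, OOB indices, prediction and evaluation."""

    def __init__(self, model: RandomForest, trees, oob_indices, seed: int):
        self.model = model
        self.trees = list(trees)
        self.oob_indices = list(oob_indices)
        self.seed = seed
        self.feature_names = model.feature_names
        self.y_train_min = float(model.endog.min())
        self.y_train_max = float(model.endog.max())

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, X) -> np.ndarray:
        """Mean over trees; every prediction lies within the training range."""
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        out = np.zeros(X.shape[0], dtype=np.float64)
        for tree in self.trees:
            _cart._predict_tree(
                tree.feature, tree.threshold, tree.left, tree.right, tree.value, X, out
            )
        return out / len(self.trees)

    def evaluate(self, X, y) -> EvalMetrics:
        """MAE and Pearson r of forest predictions against observations."""
        return evaluate_pairs(self.predict(X), y)

    def oob_prediction(self) -> np.ndarray:
        """Out-of-bag prediction per training record (NaN if never OOB)."""
        n = self.model.exog.shape[0]
        acc = np.zeros(n)
        cnt = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_indices):
            if oob.size == 0:
                continue
            acc[oob] += tree.predict(self.model.exog[oob])
            cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    def summary(self) -> str:
        cfg = self.model.config
        n, f = self.model.exog.shape
        train = self.evaluate(self.model.exog, self.model.endog)
        lines = [
            "Random forest regression results",
            "=" * 40,
            f"records (training)     {n}",
            f"features               {f}",
            f"trees                  {self.n_trees}",
            f"mtry                   {cfg.resolve_mtry(f)}",
            f"min_leaf               {cfg.min_leaf}",
            f"bootstrap              {cfg.bootstrap}",
            f"seed                   {self.seed}",
            f"training MAE           {train.mae:.4g}",
            f"training Pearson r     {train.pearson_r:.4g}"
            if train.correlation_defined
            else "training Pearson r     undefined",
        ]
        return "\n".join(lines)


# -- functional wrappers --------------------------------------------------

def fit_forest(X, y, config: Optional[ForestConfig] = None,
               feature_names=None) -> RandomForestResults:
    """Fit a regression forest on (X, y); see :class:`RandomForest`."""
    return RandomForest(y, X, feature_names=feature_names, config=config).fit()


def predict(forest: RandomForestResults, X) -> np.ndarray:
    return forest.predict(X)


def evaluate(forest: RandomForestResults, X_test, y_test) -> EvalMetrics:
    return forest.evaluate(X_test, y_test)


# -- serialization --------------------------------------------------------

def save_forest(forest: RandomForestResults, path) -> None:
    """Write the fitted ensemble to a JSON text file (nested node records)."""
    cfg = forest.model.config
    payload = {
        "format": "mbdforest-forest-v1",
        "feature_names": forest.feature_names,
        "seed": forest.seed,
        "config": {
            "n_trees": cfg.n_trees,
            "mtry": cfg.mtry,
            "min_leaf": cfg.min_leaf,
            "max_depth": cfg.max_depth,
            "bootstrap": cfg.bootstrap,
            "seed": cfg.seed,
        },
        "y_train_min": forest.y_train_min,
        "y_train_max": forest.y_train_max,
        "trees": [t.to_dict() for t in forest.trees],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


class _LoadedForest(RandomForestResults):
    """A forest re-hydrated from disk (no training data attached)."""

    def __init__(self, feature_names, trees, config, seed, y_min, y_max):
        self.model = None
        self.trees = trees
        self.oob_indices = [np.empty(0, dtype=np.int64) for _ in trees]
        self.seed = seed
        self.feature_names = feature_names
        self.config = config
        self.y_train_min = y_min
        self.y_train_max = y_max

    def summary(self) -> str:  # pragma: no cover - convenience only
        return f"Loaded forest: {self.n_trees} trees, {len(self.feature_names)} features"


def load_forest(path) -> RandomForestResults:
    """Read a forest written by :func:`save_forest`."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "mbdforest-forest-v1":
        raise ValueError("not a mbdforest forest file")
    cfg = ForestConfig(**payload["config"])
    trees = [RegressionTree.from_dict(d) for d in payload["trees"]]
    return _LoadedForest(
        payload["feature_names"], trees, cfg, payload["seed"],
        payload["y_train_min"], payload["y_train_max"],
    )
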
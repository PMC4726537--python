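"""Single CART regression trees: split search, growth, prediction.

Trees are axis-aligned binary regression trees grown by variance reduction.
A record goes left when ``x[feature] <= threshold``.  Leaf values are the
mean training response in the leaf, so every prediction lies within the
range of the training responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _cart


@dataclass
class TreeConfig:
    """Growth parameters for a single regression tree.

    mtry
        Number of candidate features drawn (without replacement) at each
        node.  ``None`` means all features (deterministic CART).
    min_leaf
        Minimum number of training records in each child of a split.
    max_depth
        Maximum depth of the tree; ``None`` is unbounded.  Depth 0 yields a
        single leaf holding the global training mean.
    """

    mtry: Optional[int] = None
    min_leaf: int = 5
    max_depth: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")


class RegressionTree:
    """A fitted regression tree stored as flat node arrays.

    Internal nodes carry ``(feature, threshold)``; leaves carry the mean of
    their training responses.  ``feature == -1`` marks a leaf.
    """

    def __init__(self, feature, threshold, left, right, value, n_node):
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=np.float64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.value = np.asarray(value, dtype=np.float64)
        self.n_node = np.asarray(n_node, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature == _cart._LEAF))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
        out = np.zeros(X.shape[0], dtype=np.float64)
        _cart._predict_tree(
            self.feature, self.threshold, self.left, self.right, self.value, X, out
        )
        return out

    # -- serialization (nested-record text form) --------------------------
    def to_dict(self, node: int = 0) -> dict:
        if self.feature[node] < 0:
            return {"value": float(self.value[node]), "n": int(self.n_node[node])}
        return {
            "feature": int(self.feature[node]),
            "threshold": float(self.threshold[node]),
            "n": int(self.n_node[node]),
            "left": self.to_dict(int(self.left[node])),
            "right": self.to_dict(int(self.right[node])),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        feature, threshold, left, right, value, n_node = [], [], [], [], [], []

        def build(nd: dict) -> int:
            i = len(feature)
            feature.append(-1)
            threshold.append(0.0)
            left.append(-1)
            right.append(-1)
            value.append(nd.get("value", 0.0))
            n_node.append(nd.get("n", 0))
            if "feature" in nd:
                feature[i] = nd["feature"]
                threshold[i] = nd["threshold"]
                left[i] = build(nd["left"])
                right[i] = build(nd["right"])
            return i

        build(d)
        return cls(feature, threshold, left, right, value, n_node)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegressionTree):
            return NotImplemented
        return (
            np.array_equal(self.feature, other.feature)
            and np.array_equal(self.threshold, other.threshold)
            and np.array_equal(self.left, other.left)
            and np.array_equal(self.right, other.right)
            and np.array_equal(self.value, other.value)
        )


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidate_features: Optional[Sequence[int]] = None,
    min_leaf: int = 1,
):
    """Exhaustive best variance-reduction split over candidate features.

    Scans the midpoints between consecutive distinct sorted values of each
    candidate feature and returns the ``(feature, threshold, sse_reduction)``
    triple minimising the total child SSE, or ``None`` when y is constant or
    no cut leaves at least ``min_leaf`` records on both sides.  SSE ties are
    broken towards the lowest feature index, then the lowest threshold.
    """
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of records")
    if X.shape[0] < 2:
        return None
    if candidate_features is None:
        feats = np.arange(X.shape[1], dtype=np.int64)
    else:
        feats = np.sort(np.asarray(candidate_features, dtype=np.int64))
    idx = np.arange(X.shape[0], dtype=np.int64)
    feat, thr, red = _cart._best_split(X, y, idx, 0, X.shape[0], feats, min_leaf)
    if feat < 0:
        return None
    return int(feat), float(thr), float(red)


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    config: Optional[TreeConfig] = None,
    rng: Optional[np.random.Generator | int] = None,
    sample_idx: Optional[np.ndarray] = None,
) -> RegressionTree:
    """Grow a regression tree on (X, y).

    ``rng`` seeds the per-node feature subsampling; it may be an integer or
    a ``numpy.random.Generator`` (one 31-bit seed is drawn from it).  When
    ``mtry`` equals the number of features the tree is the deterministic
    exhaustive CART regardless of the seed.
    """
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.shape[0] == 0:
        raise ValueError("cannot grow a tree on an empty table")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of records")
    config = config or TreeConfig()
    n_features = X.shape[1]
    mtry = n_features if config.mtry is None else min(config.mtry, n_features)
    max_depth = (1 << 60) if config.max_depth is None else config.max_depth
    if rng is None:
        seed = 0
    elif isinstance(rng, (int, np.integer)):
        seed = int(rng) % (2**31 - 1)
    else:
        seed = int(rng.integers(0, 2**31 - 1))
    if sample_idx is None:
        sample_idx = np.arange(X.shape[0], dtype=np.int64)
    else:
        sample_idx = np.asarray(sample_idx, dtype=np.int64)
    arrays = _cart._grow(X, y, sample_idx, mtry, config.min_leaf, max_depth, seed)
    return RegressionTree(*arrays)


def tree_mse(tree: RegressionTree, X: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error of a tree's predictions on (X, y)."""
    resid = tree.predict(X) - np.asarray(y, dtype=np.float64)
    return float(np.mean(resid**2))
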
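"""Shared fixtures and the independent brute-force CART oracle.

The oracle grows regression trees by naive exhaustive enumeration
(O(n^2 * f) per node) with the same contract as the package's grower:
variance-reduction splits at midpoints of consecutive distinct values,
ties broken by lowest feature index then lowest threshold, leaves hold the
training mean.  It shares no code with the production tree engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mbdforest import CohortConfig, generate_cohort


# -- brute-force oracle ---------------------------------------------------

def _sse(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2))


def oracle_best_split(X: np.ndarray, y: np.ndarray, min_leaf: int = 1):
    """Exhaustive best split by direct SSE evaluation of every cut."""
    n, f = X.shape
    if n < 2 or np.all(y == y[0]):
        return None
    best = None
    for j in range(f):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = 0.5 * (a + b)
            left = X[:, j] <= thr
            nl = int(left.sum())
            if nl < min_leaf or n - nl < min_leaf:
                continue
            sse = _sse(y[left]) + _sse(y[~left])
            if best is None or sse < best[0]:
                best = (sse, j, thr)
    if best is None:
        return None
    sse, j, thr = best
    return j, thr, _sse(y) - sse


class OracleTree:
    """Recursive brute-force CART (deterministic, all features)."""

    def __init__(self, X, y, min_leaf=1, max_depth=None, depth=0):
        self.value = float(np.mean(y))
        self.split = None
        if max_depth is not None and depth >= max_depth:
            return
        if len(y) < 2 * min_leaf:
            return
        found = oracle_best_split(X, y, min_leaf)
        if found is None:
            return
        j, thr, _ = found
        left = X[:, j] <= thr
        self.split = (j, thr)
        self.left = OracleTree(X[left], y[left], min_leaf, max_depth, depth + 1)
        self.right = OracleTree(X[~left], y[~left], min_leaf, max_depth, depth + 1)

    def predict_one(self, x):
        node = self
        while node.split is not None:
            j, thr = node.split
            node = node.left if x[j] <= thr else node.right
        return node.value

    def predict(self, X):
        return np.array([self.predict_one(x) for x in np.atleast_2d(X)])


@pytest.fixture
def oracle_tree_cls():
    return OracleTree


# -- cohort fixtures ------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A small default-structure cohort (150 patients x 6 months)."""
    return generate_cohort(CohortConfig(n_patients=150, months_per_patient=6, seed=42))


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One full-size default cohort (1758 patients x 26 months)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture
def step_data():
    """Tiny table with a clean step signal in feature 0 and noise in 1."""
    rng = np.random.default_rng(0)
    X = np.column_stack([np.array([1.0, 2.0, 3.0, 4.0]), rng.normal(size=4)])
    y = np.array([0.0, 0.0, 10.0, 10.0])
    return X, y
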
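"""Drop-feature importance and pairwise error comparison.

The relevance of an input variable is measured in the output's clinical
units: the forest is refit with that column removed (same seed, same
split) and the increase in test-set mean absolute error over the full
model is the variable's importance.  Per-record absolute errors are kept
so that any two reduced models can be compared with a paired test on
shared test records, mirroring the significance matrices clinicians read
for each output variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import FeatureMatrix, SplitIndices
from .forest import ForestConfig, RandomForest

__all__ = [
    "ImportanceTable",
    "PairwiseComparison",
    "drop_feature_importance",
    "permutation_importance",
    "pairwise_error_comparison",
]


@dataclass
class ImportanceTable:
    """Per-feature increase in test MAE when the feature is dropped.

    ``delta_mae[f] = mae_without_f - baseline_mae``; negative values can
    occur for noise features.  ``errors`` retains the per-test-record
    absolute errors of each reduced model (and ``baseline_errors`` those of
    the full model) for paired significance testing.
    """

    output_name: str
    baseline_mae: float
    delta_mae: Dict[str, float]
    baseline_errors: np.ndarray
    errors: Dict[str, np.ndarray]
    mode: str = "drop"

    def ranking(self) -> List[str]:
        """Features sorted by decreasing importance."""
        return sorted(self.delta_mae, key=self.delta_mae.get, reverse=True)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": list(self.delta_mae),
                "delta_mae": [self.delta_mae[f] for f in self.delta_mae],
            }
        )
        df["baseline_mae"] = self.baseline_mae
        df["mae_without"] = df["baseline_mae"] + df["delta_mae"]
        return df.sort_values("delta_mae", ascending=False).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PairwiseComparison:
    """Symmetric matrix of p-values comparing reduced-model errors.

    Entry (j, k) tests, on the shared test records, whether the absolute
    errors of the model without feature j differ from those of the model
    without feature k (paired two-sided test; diagonal is NaN).
    """

    p_matrix: pd.DataFrame
    test_name: str
    alpha: float = 0.05
    adjusted: bool = False

    def significant(self) -> pd.DataFrame:
        return self.p_matrix < self.alpha

    def to_csv(self, path) -> None:
        """Write the matrix with only the upper triangle populated."""
        out = self.p_matrix.copy()
        mask = np.tril(np.ones(out.shape, dtype=bool))
        out.values[mask] = np.nan
        out.to_csv(path)


def _fit_and_errors(
    matrix: FeatureMatrix, split: SplitIndices, config: ForestConfig
) -> np.ndarray:
    model = RandomForest.from_feature_matrix(matrix, config, train_idx=split.train_idx)
    res = model.fit(seed=config.seed)
    pred = res.predict(matrix.X[split.test_idx])
    return np.abs(pred - matrix.y[split.test_idx])


def drop_feature_importance(
    matrix: FeatureMatrix,
    split: SplitIndices,
    config: Optional[ForestConfig] = None,
    features: Optional[List[str]] = None,
) -> ImportanceTable:
    """Refit-without-column importance for every feature (deterministic
    given ``config.seed``).

    For each feature the forest is refit on the training records with that
    column removed and evaluated on the same test records; the same seed is
    reused throughout so the only difference between models is the dropped
    column.
    """
    if matrix.X.shape[1] < 2:
        raise ValueError("importance needs at least 2 features")
    config = config or ForestConfig()
    features = list(features) if features is not None else list(matrix.feature_names)
    base_errors = _fit_and_errors(matrix, split, config)
    baseline_mae = float(base_errors.mean())
    delta: Dict[str, float] = {}
    errors: Dict[str, np.ndarray] = {}
    for name in features:
        reduced = matrix.drop_feature(name)
        errs = _fit_and_errors(reduced, split, config)
        errors[name] = errs
        delta[name] = float(errs.mean()) - baseline_mae
    return ImportanceTable(
        matrix.output_name, baseline_mae, delta, base_errors, errors, mode="drop"
    )


def permutation_importance(
    matrix: FeatureMatrix,
    split: SplitIndices,
    config: Optional[ForestConfig] = None,
    features: Optional[List[str]] = None,
    perm_seed: int = 0,
) -> ImportanceTable:
    """Secondary importance mode: permute a column in the test records
    instead of refitting without it (one fit, cheaper, different
    estimand)."""
    if matrix.X.shape[1] < 2:
        raise ValueError("importance needs at least 2 features")
    config = config or ForestConfig()
    features = list(features) if features is not None else list(matrix.feature_names)
    model = RandomForest.from_feature_matrix(matrix, config, train_idx=split.train_idx)
    res = model.fit(seed=config.seed)
    X_test = matrix.X[split.test_idx]
    y_test = matrix.y[split.test_idx]
    base_errors = np.abs(res.predict(X_test) - y_test)
    baseline_mae = float(base_errors.mean())
    rng = np.random.default_rng(perm_seed)
    delta: Dict[str, float] = {}
    errors: Dict[str, np.ndarray] = {}
    for name in features:
        j = matrix.feature_names.index(name)
        Xp = X_test.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        errs = np.abs(res.predict(Xp) - y_test)
        errors[name] = errs
        delta[name] = float(errs.mean()) - baseline_mae
    return ImportanceTable(
        matrix.output_name, baseline_mae, delta, base_errors, errors, mode="permute"
    )


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a flat p-value vector."""
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def pairwise_error_comparison(
    table: ImportanceTable,
    test: str = "wilcoxon",
    alpha: float = 0.05,
    holm: bool = False,
) -> PairwiseComparison:
    """Paired two-sided test of per-record absolute errors for every
    feature pair.

    ``test`` is ``"wilcoxon"`` (signed-rank, default) or ``"ttest"``
    (paired t).  p-values are reported raw by default; ``holm=True``
    applies a Holm step-down adjustment across the upper triangle.
    """
    names = list(table.errors)
    lengths = {len(v) for v in table.errors.values()}
    if len(lengths) != 1:
        raise ValueError("per-feature error vectors have mismatched lengths")
    k = len(names)
    p_mat = np.full((k, k), np.nan)
    pairs = []
    for a in range(k):
        for b in range(a + 1, k):
            d = table.errors[names[a]] - table.errors[names[b]]
            if np.allclose(d, 0.0):
                p = 1.0
            elif test == "wilcoxon":
                p = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
            elif test == "ttest":
                p = float(stats.ttest_rel(table.errors[names[a]], table.errors[names[b]]).pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            pairs.append((a, b, p))
    if holm and pairs:
        adj = _holm(np.array([p for _, _, p in pairs]))
        pairs = [(a, b, float(q)) for (a, b, _), q in zip(pairs, adj)]
    for a, b, p in pairs:
        p_mat[a, b] = p
        p_mat[b, a] = p
    return PairwiseComparison(
        pd.DataFrame(p_mat, index=names, columns=names),
        test_name=test,
        alpha=alpha,
        adjusted=holm,
    )


def plot_importance(table: ImportanceTable, path, significant: Optional[set] = None):
    """Bar chart of delta-MAE per feature (output units); features whose
    pairwise comparisons are significant can be highlighted."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = table.to_frame()
    colors = [
        "tab:red" if significant and f in significant else "tab:blue"
        for f in df["feature"]
    ]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.bar(df["feature"], df["delta_mae"], color=colors)
    ax.set_ylabel(f"increase in MAE ({table.output_name})")
    ax.set_title(f"Drop-feature importance for {table.output_name}")
    ax.tick_params(axis="x", rotation=75)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
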
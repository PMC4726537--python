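"""Counterfactual perturbation analysis and the marginal baseline.

Two views of the same association: the classical Pearson correlation
between two observed variables (e.g. phosphate and PTH), and the
model-based counterfactual response — shift one input by a random delta
while holding every other feature fixed, and correlate the imposed deltas
with the resulting change in the model's prediction.  The responses are
model-based "what-ifs", not estimated causal effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import FeatureMatrix
from .forest import EvalMetrics, format_p_value

__all__ = [
    "PerturbationConfig",
    "PerturbationResult",
    "marginal_correlation",
    "perturbation_response",
    "response_band",
]


@dataclass
class PerturbationConfig:
    """Settings for a perturbation run.

    One delta per selected record is drawn uniformly from
    ``[delta_low, delta_high]`` (defaults -3 to +3, phosphate units of
    mg/dL); perturbed values below ``clamp_floor`` are clamped there and
    counted.
    """

    target_feature: str = "p"
    delta_low: float = -3.0
    delta_high: float = 3.0
    clamp_floor: float = 0.5
    seed: int = 0
    n_draws: int = 1  # >1 repeats draws per record for variance estimation

    def __post_init__(self) -> None:
        if not self.delta_low < self.delta_high:
            raise ValueError("delta_low must be below delta_high")
        if self.clamp_floor <= 0:
            raise ValueError("clamp_floor must be positive")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


@dataclass
class PerturbationResult:
    """Paired (imposed delta, predicted response) samples."""

    deltas: np.ndarray
    responses: np.ndarray
    pearson_r: float
    p_value: float
    n: int
    n_clamped: int
    target_feature: str
    record_idx: np.ndarray = field(default=None)
    correlation_defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_index": self.record_idx
                if self.record_idx is not None
                else np.arange(self.n),
                "delta": self.deltas,
                "response": self.responses,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        r = f"{self.pearson_r:.3f}" if self.correlation_defined else "undefined"
        return (
            f"Perturbation of {self.target_feature!r}: n={self.n}, "
            f"r={r} (p {format_p_value(self.p_value)}), "
            f"{self.n_clamped} perturbed values clamped"
        )


def marginal_correlation(table, var_a: str, var_b: str) -> Tuple[float, float]:
    """Pearson correlation between two observed variables (raw values).

    The classical single-pair view of an association; returns (r, p).
    """
    a = np.asarray(table[var_a], dtype=float)
    b = np.asarray(table[var_b], dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def perturbation_response(
    forest,
    matrix: FeatureMatrix,
    config: Optional[PerturbationConfig] = None,
    records: Optional[np.ndarray] = None,
) -> PerturbationResult:
    """Impose random deltas on one input and record the prediction change.

    For each selected record a delta is drawn uniformly from the configured
    range, added to the target feature (all other columns untouched), and
    the response is the difference between the perturbed and the original
    model prediction.  Returns the paired samples with their Pearson
    correlation; seed-deterministic.
    """
    config = config or PerturbationConfig()
    if config.target_feature not in matrix.feature_names:
        raise ValueError(f"target feature {config.target_feature!r} not in matrix")
    if records is None:
        records = np.arange(matrix.n)
    records = np.asarray(records, dtype=np.int64)
    if records.size == 0:
        raise ValueError("empty record set")
    if config.n_draws > 1:
        records = np.repeat(records, config.n_draws)

    j = matrix.feature_names.index(config.target_feature)
    rng = np.random.default_rng(config.seed)
    deltas = rng.uniform(config.delta_low, config.delta_high, size=records.size)

    X0 = matrix.X[records]
    X1 = X0.copy()
    perturbed = X1[:, j] + deltas
    clamped = perturbed < config.clamp_floor
    perturbed = np.maximum(perturbed, config.clamp_floor)
    X1[:, j] = perturbed
    # report the delta actually applied after clamping
    deltas = perturbed - X0[:, j]

    responses = forest.predict(X1) - forest.predict(X0)
    if np.ptp(responses) == 0.0 or np.ptp(deltas) == 0.0 or records.size < 3:
        r, p, defined = float("nan"), float("nan"), False
    else:
        r, p = stats.pearsonr(deltas, responses)
        r, p, defined = float(r), float(p), True
    return PerturbationResult(
        deltas=deltas,
        responses=responses,
        pearson_r=r,
        p_value=p,
        n=int(records.size),
        n_clamped=int(clamped.sum()),
        target_feature=config.target_feature,
        record_idx=records,
        correlation_defined=defined,
    )


def response_band(
    result: PerturbationResult, delta_query: float, tol: float = 0.25
) -> Tuple[float, float]:
    """Empirical (min, max) response among samples with deltas within
    ``tol`` of ``delta_query`` — the vertical spread of the perturbation
    scatter, expressing between-record heterogeneity of the response.
    """
    if delta_query < result.deltas.min() - tol or delta_query > result.deltas.max() + tol:
        raise ValueError("delta_query outside the sampled delta range")
    near = np.abs(result.deltas - delta_query) <= tol
    if int(near.sum()) < 10:
        raise ValueError(
            f"only {int(near.sum())} samples within {tol} of delta={delta_query}; need >= 10"
        )
    r = result.responses[near]
    return float(r.min()), float(r.max())


def plot_perturbation(table, result: PerturbationResult, path,
                      var_a: str = "p", var_b: str = "pth"):
    """Two-panel figure: observed scatter of (var_a, var_b) with its
    marginal correlation, and the (delta, response) perturbation scatter."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    r_marg, _ = marginal_correlation(table, var_a, var_b)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
    ax1.scatter(table[var_a], table[var_b], s=4, alpha=0.25)
    ax1.set_xlabel(var_a)
    ax1.set_ylabel(var_b)
    ax1.set_title(f"Observed: r = {r_marg:.2f}")
    ax2.scatter(result.deltas, result.responses, s=4, alpha=0.25)
    r_txt = f"{result.pearson_r:.2f}" if result.correlation_defined else "undefined"
    ax2.set_xlabel(f"imposed change in {result.target_feature}")
    ax2.set_ylabel("predicted change in output")
    ax2.set_title(f"Counterfactual: r = {r_txt}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
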
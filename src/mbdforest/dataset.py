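"""Loading, filtering and encoding of record tables.

Turns a cohort record table into the numeric design used by the models:
complete-case filtering, 0/1 encoding of gender and drug exposure, and a
random 70/30 train/test split at the record level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .cohort import COLUMNS, DRUG_COLUMNS, REQUIRED_FIELDS

logger = logging.getLogger(__name__)

OUTPUTS = ("ca", "p", "pth")
BIOCHEM_CANDIDATES = ["ca", "p", "pth"]


@dataclass
class FeatureMatrix:
    """Numeric design matrix for one output variable.

    ``X`` holds one column per retained input feature in the documented
    order; ``y`` is the output variable (one of ca / p / pth), which never
    appears among the features.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: List[str]
    output_name: str

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        self.y = np.ascontiguousarray(self.y, dtype=np.float64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X")
        if self.output_name in self.feature_names:
            raise ValueError("output variable leaked into the feature set")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def drop_feature(self, name: str) -> "FeatureMatrix":
        """Copy of the matrix without one feature column."""
        if name not in self.feature_names:
            raise KeyError(f"unknown feature {name!r}")
        j = self.feature_names.index(name)
        keep = [k for k in range(self.X.shape[1]) if k != j]
        names = [f for f in self.feature_names if f != name]
        return FeatureMatrix(self.X[:, keep], self.y, names, self.output_name)

    def to_frame(self) -> pd.DataFrame:
        """Reassemble features plus the output column as a DataFrame."""
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df[self.output_name] = self.y
        return df


@dataclass
class SplitIndices:
    """Record-level train/test partition (disjoint, exhaustive)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    train_fraction: float = 0.7

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.test_idx = np.asarray(self.test_idx, dtype=np.int64)
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")

    @property
    def n(self) -> int:
        return self.train_idx.size + self.test_idx.size

    def to_csv(self, path) -> None:
        idx = np.concatenate([self.train_idx, self.test_idx])
        role = ["train"] * self.train_idx.size + ["test"] * self.test_idx.size
        pd.DataFrame({"record_index": idx, "role": role}).to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    """Read a record-table CSV in the documented dialect.

    Missing required columns raise; unknown extra columns are warned about
    and kept; non-numeric biochemistry raises with the offending line
    numbers (1-based, counting the header as line 1).
    """
    table = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in table.columns if c not in COLUMNS]
    if extra:
        warnings.warn(f"ignoring unknown extra column(s): {', '.join(extra)}")
    numeric_cols = [c for c in COLUMNS if c != "patient_id"]
    for c in numeric_cols:
        coerced = pd.to_numeric(table[c], errors="coerce")
        bad = coerced.isna() & table[c].notna()
        if bad.any():
            lines = [str(i + 2) for i in table.index[bad][:10]]
            raise ValueError(
                f"non-numeric values in column {c!r} at line(s) {', '.join(lines)}"
            )
        table[c] = coerced
    return table


def filter_complete(table: pd.DataFrame) -> pd.DataFrame:
    """Keep only records with every required field present (complete-case).

    Idempotent; the number of dropped records is logged.  An empty result
    is allowed but warned about.
    """
    present = [c for c in REQUIRED_FIELDS if c in table.columns]
    mask = table[present].notna().all(axis=1)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("filter_complete: dropped %d of %d records", dropped, len(table))
    out = table.loc[mask].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("filter_complete produced an empty table")
    return out


def feature_list(
    output_name: str,
    include_potassium: bool = True,
    include_time: bool = True,
) -> List[str]:
    """Ordered input-feature names for a given output variable.

    The default design keeps the two non-output biochemical variables,
    alkaline phosphatase, potassium, age, gender, vintage, the month index
    and the eight drug flags (15 features for any output).  The
    figure-replication preset (``include_potassium=False,
    include_time=False``) drops potassium and time.
    """
    if output_name not in OUTPUTS:
        raise ValueError(f"output_name must be one of {OUTPUTS}, got {output_name!r}")
    feats = [b for b in BIOCHEM_CANDIDATES if b != output_name]
    feats.append("alk_phos")
    if include_potassium:
        feats.append("potassium")
    feats += ["age", "gender", "vintage"]
    if include_time:
        feats.append("month_index")
    feats += DRUG_COLUMNS
    return feats


def encode_features(
    table: pd.DataFrame,
    output_name: str,
    include_potassium: bool = True,
    include_time: bool = True,
) -> FeatureMatrix:
    """Encode a complete record table as a numeric feature matrix.

    Gender is 0/1 (male = 1) and drug flags pass through as 0/1; column
    order is fixed by :func:`feature_list`.
    """
    feats = feature_list(output_name, include_potassium, include_time)
    missing = [c for c in feats + [output_name] if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks column(s): {', '.join(missing)}")
    X = table[feats].to_numpy(dtype=np.float64)
    y = table[output_name].to_numpy(dtype=np.float64)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values present; run filter_complete first")
    return FeatureMatrix(X, y, feats, output_name)


def split_train_test(
    matrix_or_n,
    seed: int,
    train_fraction: float = 0.7,
    by_patient: Optional[np.ndarray] = None,
) -> SplitIndices:
    """Uniform random 70/30 record split (seed-deterministic).

    ``by_patient`` optionally supplies a patient id per record, in which
    case whole patients are assigned to one side (leakage-free variant);
    the default record-level split mirrors the standard protocol of
    sampling records irrespective of patient.
    """
    n = matrix_or_n if isinstance(matrix_or_n, (int, np.integer)) else matrix_or_n.n
    if n < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    if by_patient is not None:
        by_patient = np.asarray(by_patient)
        patients = np.unique(by_patient)
        perm = rng.permutation(patients)
        n_train_pat = int(round(train_fraction * patients.size))
        train_pat = set(perm[:n_train_pat].tolist())
        mask = np.array([pid in train_pat for pid in by_patient])
        train = np.flatnonzero(mask)
        test = np.flatnonzero(~mask)
    else:
        perm = rng.permutation(n)
        n_train = int(round(train_fraction * n))
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
    return SplitIndices(train, test, seed, train_fraction)
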
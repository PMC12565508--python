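"""Leakage-free transforms: IQR capping, log features, log1p target, stratified folds.

Every fit-like operation here (quartiles, fences) is computed from training
rows only and stored in a serialisable artifact that is then *applied* to
held-out rows — the contract that keeps cross-validation honest.  The target
is modelled on a log scale, y = log(1 + volume_mL), to tame the
heteroscedastic growth of errors with fruit size; predictions are mapped
back with exp(y) - 1 before any metric is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CappingBounds",
    "FoldAssignment",
    "fit_iqr_caps",
    "apply_caps",
    "winsorize_log_features",
    "transform_target",
    "inverse_transform_target",
    "stratified_folds",
]

IQR_K = 1.5  # conventional outlier-fence multiplier
DEFAULT_FOLDS = 5
DEFAULT_BINS = 5


@dataclass(frozen=True)
class CappingBounds:
    """Per-column quartiles and outlier fences fitted on training data."""

    columns: tuple[str, ...]
    q1: tuple[float, ...]
    q3: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    k: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "columns": list(self.columns),
                "q1": list(self.q1),
                "q3": list(self.q3),
                "lower": list(self.lower),
                "upper": list(self.upper),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CappingBounds":
        d = json.loads(text)
        return cls(
            columns=tuple(d["columns"]),
            q1=tuple(d["q1"]),
            q3=tuple(d["q3"]),
            lower=tuple(d["lower"]),
            upper=tuple(d["upper"]),
            k=d["k"],
        )


@dataclass(frozen=True)
class FoldAssignment:
    """Quantile-stratified k-fold partition of a target vector."""

    k: int
    bin_count: int
    fold_index: tuple[int, ...]
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_index) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.fold_index) != fold)


def fit_iqr_caps(table: pd.DataFrame, k: float = IQR_K) -> CappingBounds:
    """Fit per-column quartiles (linear interpolation) and Tukey fences.

    A constant column has IQR 0 and degenerate fences equal to the constant,
    making capping a no-op there.  Fit on training rows only.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 training rows to fit quartiles")
    if k < 0:
        raise ValueError("IQR multiplier must be non-negative")
    cols, q1s, q3s, los, his = [], [], [], [], []
    for col in table.columns:
        x = np.asarray(table[col], dtype=float)
        q1, q3 = np.quantile(x, [0.25, 0.75])  # linear interpolation
        iqr = q3 - q1
        cols.append(col)
        q1s.append(float(q1))
        q3s.append(float(q3))
        los.append(float(q1 - k * iqr))
        his.append(float(q3 + k * iqr))
    return CappingBounds(tuple(cols), tuple(q1s), tuple(q3s), tuple(los), tuple(his), k)


def apply_caps(table: pd.DataFrame, bounds: CappingBounds) -> pd.DataFrame:
    """Clip each fitted column into [lower, upper]; idempotent."""
    missing = set(bounds.columns) - set(table.columns)
    if missing:
        raise KeyError(f"columns missing from table: {sorted(missing)}")
    out = table.copy()
    for col, lo, hi in zip(bounds.columns, bounds.lower, bounds.upper):
        out[col] = np.clip(out[col].astype(float), lo, hi)
    return out


def winsorize_log_features(table: pd.DataFrame, log_columns: list[str]) -> pd.DataFrame:
    """Natural-log the designated strictly-positive columns; leave the rest.

    Ratio-type features (aspect ratios, eccentricities, sphericity) stay on
    their natural scale; sizes, areas, volumes, perimeters and interactions
    are logged.  Raises naming the offending column/row on a non-positive
    value in a log column.
    """
    out = table.copy()
    for col in log_columns:
        if col not in out.columns:
            raise KeyError(f"log column {col!r} not in table")
        x = np.asarray(out[col], dtype=float)
        if np.any(x <= 0):
            row = int(np.flatnonzero(x <= 0)[0])
            raise ValueError(f"non-positive value in log column {col!r} at row {row}")
        out[col] = np.log(x)
    return out


def transform_target(volume_ml):
    """y = log(1 + volume); defined for volume >= 0."""
    v = np.asarray(volume_ml, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be non-negative")
    return np.log1p(v)


def inverse_transform_target(y_hat):
    """volume = exp(y) - 1, the exact inverse of the log1p transform."""
    return np.expm1(np.asarray(y_hat, dtype=float))


def stratified_folds(
    targets,
    k: int = DEFAULT_FOLDS,
    bins: int = DEFAULT_BINS,
    seed: int = 0,
) -> FoldAssignment:
    """Quantile-stratified k-fold assignment.

    Targets are binned into ``bins`` empirical-quantile groups; within each
    bin the members are shuffled (seeded) and dealt round-robin across folds,
    with a global running counter so overall fold sizes differ by at most 1.
    """
    y = np.asarray(targets, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    # rank-based quantile binning; ranks break ties deterministically
    order = np.argsort(y, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    bin_id = np.minimum((ranks * bins) // n, bins - 1)
    fold_index = np.empty(n, dtype=int)
    counter = 0
    for b in range(bins):
        members = np.flatnonzero(bin_id == b)
        rng.shuffle(members)
        for m in members:
            fold_index[m] = counter % k
            counter += 1
    return FoldAssignment(k=k, bin_count=bins, fold_index=tuple(int(f) for f in fold_index), seed=seed)
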
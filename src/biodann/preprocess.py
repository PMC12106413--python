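"""Preprocessing protocol: gap filling, Z-scoring, windowing, splitting.

The pipeline is: interpolate missing cells (linear for smooth drivers such
as temperature and pH, nearest-neighbour for rougher series such as the
pollutant concentration), standardize every feature to mean 0 / sd 1 using
statistics fitted on the training rows only, cut the record into fixed-length
sliding windows with a next-step forecasting target, and split the windows
chronologically 70/15/15 into train/validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StandardizationStats",
    "WindowedDataset",
    "DataSplit",
    "fill_missing",
    "fill_table",
    "zscore_fit",
    "zscore_apply",
    "make_windows",
    "split_chronological",
    "prepare_dataset",
    "DEFAULT_INTERPOLATION",
]

TARGET_COLUMN = "pollutant_mg_per_kg"

# Nearest-neighbour for the rough series, linear for the smooth drivers.
DEFAULT_INTERPOLATION: Mapping[str, str] = {
    "pollutant_mg_per_kg": "nearest",
    "soil_moisture": "linear",
    "temperature_c": "linear",
    "ph": "linear",
    "plant_growth_index": "linear",
}


@dataclass
class StandardizationStats:
    """Per-column mean and population (1/N) standard deviation."""

    mean: dict[str, float]
    sd: dict[str, float]

    @property
    def columns(self) -> list[str]:
        return list(self.mean)

    def inverse(self, values: np.ndarray, column: str) -> np.ndarray:
        """Map standardized values of ``column`` back to original units."""
        return values * self.sd[column] + self.mean[column]


@dataclass
class WindowedDataset:
    """Sliding windows ``X`` of shape (n, T, d) with next-step targets."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    target_col: str
    T: int
    stride: int

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class DataSplit:
    """Contiguous chronological train/validation/test index ranges."""

    train: slice
    validation: slice
    test: slice

    def sizes(self) -> tuple[int, int, int]:
        return (
            self.train.stop - self.train.start,
            self.validation.stop - self.validation.start,
            self.test.stop - self.test.start,
        )


def fill_missing(
    values: Sequence[float],
    method: str = "linear",
    times: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Fill NaN gaps in a series.

    ``linear`` draws a straight line in time between the flanking observed
    values and holds edge gaps at the nearest observed value; ``nearest``
    copies the temporally closest observation, with equidistant ties going
    to the earlier neighbour.  Observed entries are never altered.
    """
    v = np.asarray(values, dtype=float)
    t = np.arange(v.size, dtype=float) if times is None else np.asarray(times, float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    observed = ~np.isnan(v)
    if not observed.any():
        raise ValueError("cannot fill an all-missing series")
    if observed.all():
        return v.copy()
    t_obs, v_obs = t[observed], v[observed]
    out = v.copy()
    missing = ~observed
    if method == "linear":
        out[missing] = np.interp(t[missing], t_obs, v_obs)
    elif method == "nearest":
        # searchsorted(..., 'right') - 1 gives the last observed point at or
        # before each gap; ties between neighbours resolve to the earlier one.
        idx = np.searchsorted(t_obs, t[missing], side="right") - 1
        idx = np.clip(idx, 0, t_obs.size - 1)
        nxt = np.clip(idx + 1, 0, t_obs.size - 1)
        d_prev = np.abs(t[missing] - t_obs[idx])
        d_next = np.abs(t_obs[nxt] - t[missing])
        choose_next = d_next < d_prev
        pick = np.where(choose_next, nxt, idx)
        out[missing] = v_obs[pick]
    else:
        raise ValueError(f"method must be 'linear' or 'nearest', got {method!r}")
    return out


def fill_table(
    table: pd.DataFrame,
    interpolation: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Fill every value column of a monitoring table per its method."""
    interpolation = dict(DEFAULT_INTERPOLATION if interpolation is None else interpolation)
    out = table.copy()
    if "timestamp" in table.columns:
        t = (
            pd.to_datetime(table["timestamp"]) - pd.to_datetime(table["timestamp"]).iloc[0]
        ).dt.total_seconds().to_numpy() / 3600.0
    else:
        t = None
    for col in table.columns:
        if col == "timestamp":
            continue
        method = interpolation.get(col, "linear")
        out[col] = fill_missing(table[col].to_numpy(dtype=float), method, times=t)
    return out


def zscore_fit(table: pd.DataFrame, columns: Sequence[str]) -> StandardizationStats:
    """Fit per-column mean and population sd; reject constant columns."""
    mean, sd = {}, {}
    for col in columns:
        v = table[col].to_numpy(dtype=float)
        m, s = float(np.mean(v)), float(np.std(v))
        if s == 0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        mean[col], sd[col] = m, s
    return StandardizationStats(mean=mean, sd=sd)


def zscore_apply(table: pd.DataFrame, stats: StandardizationStats) -> pd.DataFrame:
    """Apply fitted standardization; columns without stats pass through."""
    out = table.copy()
    for col in stats.columns:
        out[col] = (table[col].to_numpy(dtype=float) - stats.mean[col]) / stats.sd[col]
    return out


def make_windows(
    table: pd.DataFrame,
    T: int = 24,
    stride: int = 1,
    target_col: str = TARGET_COLUMN,
) -> WindowedDataset:
    """Cut a gap-free table into windows of ``T`` steps with next-step targets.

    Window ``j`` covers rows ``[j*stride, j*stride + T)`` and its target is
    the ``target_col`` value at row ``j*stride + T``.
    """
    feature_names = [c for c in table.columns if c != "timestamp"]
    if target_col not in feature_names:
        raise ValueError(f"target column {target_col!r} not in table")
    values = table[feature_names].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("table contains missing values; fill them first")
    L = values.shape[0]
    if L <= T:
        raise ValueError(f"need at least T+1={T + 1} rows, got {L}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = (L - T - 1) // stride + 1
    starts = np.arange(n) * stride
    X = np.stack([values[s : s + T] for s in starts])
    tgt = values[:, feature_names.index(target_col)]
    y = tgt[starts + T]
    return WindowedDataset(
        X=X, y=y, feature_names=feature_names, target_col=target_col, T=T, stride=stride
    )


def split_chronological(
    n_windows: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
) -> DataSplit:
    """Split windows chronologically; floor counts, remainder to test."""
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_train = int(np.floor(fractions[0] * n_windows))
    n_val = int(np.floor(fractions[1] * n_windows))
    n_test = n_windows - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"split of {n_windows} windows at {fractions} leaves an empty set"
        )
    return DataSplit(
        train=slice(0, n_train),
        validation=slice(n_train, n_train + n_val),
        test=slice(n_train + n_val, n_windows),
    )


def prepare_dataset(
    table: pd.DataFrame,
    T: int = 24,
    stride: int = 1,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    target_col: str = TARGET_COLUMN,
    interpolation: Optional[Mapping[str, str]] = None,
) -> tuple[WindowedDataset, DataSplit, StandardizationStats]:
    """Run the full preprocessing protocol on a raw monitoring table.

    Standardization statistics are fitted only on the rows that feed the
    training windows and their targets, so no validation/test information
    leaks into the transform.
    """
    filled = fill_table(table, interpolation)
    feature_names = [c for c in filled.columns if c != "timestamp"]
    L = len(filled)
    if L <= T:
        raise ValueError(f"need at least T+1={T + 1} rows, got {L}")
    n_windows = (L - T - 1) // stride + 1
    split = split_chronological(n_windows, fractions)
    n_train = split.train.stop
    train_row_stop = (n_train - 1) * stride + T + 1
    stats = zscore_fit(filled.iloc[:train_row_stop], feature_names)
    standardized = zscore_apply(filled, stats)
    ds = make_windows(standardized, T=T, stride=stride, target_col=target_col)
    return ds, split, stats
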
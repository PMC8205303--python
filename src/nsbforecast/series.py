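"""Level-series handling: differencing, discretization, splitting, CSV I/O.

A *level series* is the raw sensor record (dissolved oxygen in mg/L at
uniform sampling). Forecasting operates on its first-order differences,
rounded to a fixed decimal precision so that each rounded difference acts
as a discrete category symbol for the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LevelSeries",
    "DifferenceSeries",
    "SeriesError",
    "first_difference",
    "reconstruct",
    "discretize",
    "round_symbol",
    "split_train_test",
    "read_level_csv",
    "write_level_csv",
]


class SeriesError(ValueError):
    """Raised for invalid series inputs (too short, NaN, misalignment)."""


@dataclass(frozen=True)
class LevelSeries:
    """An ordered continuous series (mg/L) with uniform timestamps.

    Timestamps are carried through for reporting but never enter any
    computation; irregular spacing only triggers a warning.
    """

    values: np.ndarray
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise SeriesError("level series must be one-dimensional")
        if np.isnan(values).any():
            raise SeriesError(
                "level series contains NaN values; missing data are rejected, "
                "not imputed — clean the input explicitly"
            )
        object.__setattr__(self, "values", values)
        if self.timestamps is None:
            ts = np.arange(len(values))
        else:
            ts = np.asarray(self.timestamps)
            if len(ts) != len(values):
                raise SeriesError(
                    f"timestamps ({len(ts)}) and values ({len(values)}) differ in length"
                )
            diffs = np.diff(ts)
            if len(diffs) > 0:
                if not (diffs > np.zeros(1, dtype=diffs.dtype)[0]).all():
                    raise SeriesError("timestamps must be strictly increasing")
                if len(set(np.asarray(diffs).tolist())) > 1:
                    warnings.warn(
                        "timestamps are not uniformly spaced; computations "
                        "assume uniform sampling",
                        stacklevel=3,
                    )
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DifferenceSeries:
    """First differences of a level series plus the anchor levels.

    ``diffs[t] = levels[t+1] − levels[t]``; ``anchors[t] = levels[t]`` so the
    original series is exactly recoverable as a cumulative sum from
    ``anchors[0]``.
    """

    diffs: np.ndarray
    anchors: np.ndarray

    def __len__(self) -> int:
        return len(self.diffs)


def first_difference(series: LevelSeries) -> DifferenceSeries:
    """Compute the first-order difference series of a level series.

    Raises :class:`SeriesError` if the series has fewer than two points.
    """
    if len(series) < 2:
        raise SeriesError(
            f"need at least 2 points to difference, got {len(series)}"
        )
    values = series.values
    return DifferenceSeries(diffs=np.diff(values), anchors=values[:-1].copy())


def reconstruct(
    predicted_diffs: np.ndarray | list[float], observed_levels: np.ndarray | list[float]
) -> np.ndarray:
    """Turn one-step-ahead difference predictions into level forecasts.

    Each predicted difference is added to the *observed* level at the
    current moment (walk-forward; predictions are never fed back):
    ``forecast[t] = predicted_diffs[t] + observed_levels[t]``.
    """
    predicted_diffs = np.asarray(predicted_diffs, dtype=float)
    observed_levels = np.asarray(observed_levels, dtype=float)
    if predicted_diffs.shape != observed_levels.shape:
        raise SeriesError(
            f"predicted diffs ({predicted_diffs.shape}) and observed levels "
            f"({observed_levels.shape}) are misaligned"
        )
    return predicted_diffs + observed_levels


def round_symbol(value: float, decimals: int) -> float:
    """Round one difference half-to-even to ``decimals`` places.

    Uses correctly-rounded decimal formatting so the result is bit-identical
    to parsing the fixed-precision string used in model files; −0.0 is
    normalized to +0.0 so both signs of zero are one symbol.
    """
    rounded = float(format(float(value), f".{decimals}f"))
    return 0.0 if rounded == 0.0 else rounded


def discretize(diffs: DifferenceSeries | np.ndarray, decimals: int = 2) -> np.ndarray:
    """Map continuous differences to the discrete category alphabet.

    Idempotent: discretizing already-rounded values changes nothing.
    """
    if decimals < 0:
        raise ValueError(f"decimals must be >= 0, got {decimals}")
    raw = diffs.diffs if isinstance(diffs, DifferenceSeries) else np.asarray(diffs, dtype=float)
    return np.array([round_symbol(v, decimals) for v in raw], dtype=float)


def split_train_test(series: LevelSeries, fraction: float = 0.9) -> tuple[LevelSeries, LevelSeries]:
    """Chronological split: first ``floor(fraction·m)`` points train, rest test."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"split fraction must be in (0, 1), got {fraction}")
    m = len(series)
    k = int(np.floor(fraction * m))
    if k < 2 or m - k < 2:
        raise SeriesError(
            f"split of {m} points at fraction {fraction} leaves a side with "
            "fewer than 2 points"
        )
    train = LevelSeries(series.values[:k], series.timestamps[:k])
    test = LevelSeries(series.values[k:], series.timestamps[k:])
    return train, test


def read_level_csv(path) -> LevelSeries:
    """Read a two-column ``timestamp,value`` CSV (ISO-8601 or epoch times)."""
    frame = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in frame.columns}
    if "timestamp" not in cols or "value" not in cols:
        raise SeriesError(
            f"expected columns 'timestamp,value', got {list(frame.columns)}"
        )
    ts_raw = frame[cols["timestamp"]]
    if pd.api.types.is_numeric_dtype(ts_raw):
        ts = ts_raw.to_numpy()
    else:
        ts = pd.to_datetime(ts_raw).to_numpy()
    return LevelSeries(frame[cols["value"]].to_numpy(dtype=float), ts)


def write_level_csv(series: LevelSeries, path) -> None:
    """Write the standard ``timestamp,value`` CSV."""
    pd.DataFrame({"timestamp": series.timestamps, "value": series.values}).to_csv(
        path, index=False
    )
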
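"""Daily training-load / sparse-performance time series and its CSV carrier.

The canonical on-disk format is a CSV with header ``day,load_tu,performance_w``:
one row per consecutive day starting at day 0, a nonnegative daily training
dose in training units (tu), and an optional measured performance in watts
(empty cell on days without a performance trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import IO

import numpy as np
import pandas as pd

CSV_COLUMNS = ("day", "load_tu", "performance_w")


class SeriesValidationError(ValueError):
    """Raised when a time series (or its CSV file) violates the format."""


@dataclass(frozen=True)
class TrainingTimeSeries:
    """Per-subject daily training loads plus sparse performance measurements.

    Parameters
    ----------
    loads : array of float
        Training dose in tu on days 0..N (consecutive); all finite, >= 0,
        and 0 on day 0.
    measurement_days : array of int
        Days carrying a performance measurement, strictly increasing.
    measurements : array of float
        Measured performance (watts) on those days; at least two.
    """

    loads: np.ndarray
    measurement_days: np.ndarray
    measurements: np.ndarray
    subject: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        loads = np.asarray(self.loads, dtype=float)
        days = np.asarray(self.measurement_days, dtype=int)
        meas = np.asarray(self.measurements, dtype=float)
        object.__setattr__(self, "loads", loads)
        object.__setattr__(self, "measurement_days", days)
        object.__setattr__(self, "measurements", meas)
        if loads.ndim != 1 or loads.size < 2:
            raise SeriesValidationError("loads must be a 1-d array covering >= 2 days")
        if not np.all(np.isfinite(loads)):
            raise SeriesValidationError("all loads must be finite")
        if np.any(loads < 0):
            raise SeriesValidationError("loads must be >= 0")
        if loads[0] != 0:
            raise SeriesValidationError("load on day 0 must be 0")
        if days.shape != meas.shape or days.ndim != 1:
            raise SeriesValidationError("measurement_days and measurements must align")
        if days.size < 2:
            raise SeriesValidationError("at least 2 performance measurements required")
        if np.any(np.diff(days) <= 0):
            raise SeriesValidationError("measurement days must be strictly increasing")
        if days[0] < 0 or days[-1] >= loads.size:
            raise SeriesValidationError("measurement days must lie within 0..N")
        if not np.all(np.isfinite(meas)):
            raise SeriesValidationError("measurements must be finite")

    @property
    def n_days(self) -> int:
        return int(self.loads.size)

    @property
    def n_measurements(self) -> int:
        return int(self.measurements.size)

    @property
    def perf0(self) -> float:
        """Initial performance: the first measured value (watts)."""
        return float(self.measurements[0])

    def to_frame(self) -> pd.DataFrame:
        perf = np.full(self.n_days, np.nan)
        perf[self.measurement_days] = self.measurements
        return pd.DataFrame(
            {
                "day": np.arange(self.n_days),
                "load_tu": self.loads,
                "performance_w": perf,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, subject: str | None = None) -> "TrainingTimeSeries":
        """Build a validated series from a ``day,load_tu,performance_w`` frame."""
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise SeriesValidationError(f"missing columns {missing}")
        days = frame["day"].to_numpy()
        # header is row 1; data row r of the frame is file row r + 2
        for r, (a, b) in enumerate(zip(days[:-1], days[1:])):
            if b != a + 1:
                raise SeriesValidationError(
                    f"day gap at row {r + 3} (column 'day'): day jumps from {a} to {b}"
                )
        if len(days) and days[0] != 0:
            raise SeriesValidationError("days must start at 0 (row 2, column 'day')")
        loads = pd.to_numeric(frame["load_tu"], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(loads))
        if bad.size:
            raise SeriesValidationError(
                f"malformed decimal at row {bad[0] + 2} (column 'load_tu')"
            )
        neg = np.flatnonzero(loads < 0)
        if neg.size:
            raise SeriesValidationError(
                f"negative load at row {neg[0] + 2} (column 'load_tu')"
            )
        perf_raw = frame["performance_w"]
        perf = pd.to_numeric(perf_raw, errors="coerce").to_numpy(dtype=float)
        nonempty = perf_raw.notna() & (perf_raw.astype(str).str.strip() != "")
        malformed = np.flatnonzero(nonempty.to_numpy() & ~np.isfinite(perf))
        if malformed.size:
            raise SeriesValidationError(
                f"malformed decimal at row {malformed[0] + 2} (column 'performance_w')"
            )
        mdays = np.flatnonzero(np.isfinite(perf))
        if mdays.size < 2:
            raise SeriesValidationError(
                "fewer than 2 performance measurements (column 'performance_w')"
            )
        return cls(
            loads=loads,
            measurement_days=mdays,
            measurements=perf[mdays],
            subject=subject,
        )


def read_series(path: str | PathLike | IO[str]) -> TrainingTimeSeries:
    """Read and validate a training time series from CSV.

    Validation errors name the offending file row and column.
    """
    frame = pd.read_csv(path, dtype={"day": "Int64"})
    name = getattr(path, "name", None) or (str(path) if isinstance(path, (str, PathLike)) else None)
    try:
        return TrainingTimeSeries.from_frame(frame, subject=name)
    except SeriesValidationError as err:
        raise SeriesValidationError(f"{name or 'series'}: {err}") from None


def write_series(series: TrainingTimeSeries, path: str | PathLike | IO[str]) -> None:
    """Write a series to the canonical CSV format (round-trips exactly)."""
    frame = series.to_frame()
    frame.to_csv(path, index=False, float_format="%.10g")
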
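"""Uniformly sampled time series and its CSV round trip.

``TimeSeries`` is the lingua franca between every stage of the calibration
pipeline: plunger displacement (cm), in-cylinder gauge pressure (Pa),
pneumotachograph pressure drop (Pa), corrected output volume (L) and real
output flow (L/s) all travel through it.  The on-disk form is a two-column
CSV ``time,<name>_<unit>`` with time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, SamplingError, UnitError

#: relative jitter above which a time column is rejected as non-uniform
_GRID_RTOL = 1e-6


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal with a unit label.

    Parameters
    ----------
    t0 : float
        Time of the first sample in seconds.
    dt : float
        Sample interval in seconds; must be positive.
    values : numpy.ndarray
        Sample values; one-dimensional, non-empty, all finite.
    unit : str
        Unit label, e.g. ``"Pa"``, ``"L"``, ``"L/s"``, ``"cm"``.
    meta : dict
        Free-form metadata (e.g. an ``extrapolation`` flag set by
        calibration evaluation).  Not written to CSV.
    """

    t0: float
    dt: float
    values: np.ndarray
    unit: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.isfinite(self.values).all():
            raise ValueError("all samples must be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")

    # -- derived quantities -------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n - 1)

    def copy_with(self, **kw) -> "TimeSeries":
        out = dict(t0=self.t0, dt=self.dt, values=self.values.copy(),
                   unit=self.unit, meta=dict(self.meta))
        out.update(kw)
        return TimeSeries(**out)

    def same_grid(self, other: "TimeSeries", rtol: float = 1e-9) -> bool:
        return (self.n == other.n
                and abs(self.t0 - other.t0) <= rtol * max(1.0, abs(self.t0))
                and abs(self.dt - other.dt) <= rtol * self.dt)


def read_timeseries(path, expected_unit: str | None = None) -> TimeSeries:
    """Read a two-column CSV ``time,<name>_<unit>`` into a TimeSeries.

    The sample interval is inferred from the time column; a grid whose
    relative jitter exceeds 1e-6 is rejected.  If *expected_unit* is given,
    the unit suffix of the value column must match it exactly.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "time" not in df.columns:
        raise FormatError(f"{path}: no 'time' column")
    value_cols = [c for c in df.columns if c != "time"]
    if len(value_cols) != 1:
        raise FormatError(f"{path}: expected exactly one value column, "
                          f"found {value_cols}")
    col = value_cols[0]
    if "_" not in col:
        raise FormatError(f"{path}: value column '{col}' has no unit suffix")
    unit = col.rsplit("_", 1)[1].replace("-", "/")
    if expected_unit is not None and unit != expected_unit:
        raise UnitError(f"{path}: unit '{unit}' (column '{col}'), "
                        f"expected '{expected_unit}'")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise SamplingError(f"{path}: need at least 2 samples to infer dt")
    dt = (t[-1] - t[0]) / (t.size - 1)
    if dt <= 0 or np.max(np.abs(np.diff(t) - dt)) > _GRID_RTOL * abs(dt):
        raise SamplingError(f"{path}: non-uniform or non-increasing time grid")
    return TimeSeries(t0=float(t[0]), dt=float(dt),
                      values=df[col].to_numpy(dtype=float), unit=unit)


def write_timeseries(ts: TimeSeries, path, name: str = "value") -> None:
    """Write *ts* as CSV with full float precision (round-trip safe)."""
    if not isinstance(ts, TimeSeries):
        raise ValueError("ts must be a TimeSeries")
    unit_tag = ts.unit.replace("/", "-")
    df = pd.DataFrame({"time": ts.t, f"{name}_{unit_tag}": ts.values})
    df.to_csv(path, index=False, float_format="%.17g")
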
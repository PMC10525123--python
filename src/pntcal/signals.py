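"""Measurement-chain signal processing: Butterworth low-pass filtering,
resampling of the 60 fps displacement stream onto the 250 Hz pressure grid,
and optional cross-correlation lag removal between streams.

Zero-phase (forward–backward) filtering is the default: calibration is an
offline computation and phase lag would bias the pairing of pressure drop
with flow.  A causal single-pass mode is kept for parity with live
acquisition hardware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import AlignmentError, AlignmentWarning, SamplingError
from .timeseries import TimeSeries


@dataclass
class FilterSpec:
    """Low-pass Butterworth specification.

    Defaults follow spirometric practice: 5th order, 25 Hz cutoff at a
    250 Hz sampling rate.
    """

    fs: float
    order: int = 5
    cutoff: float = 25.0
    phase: str = "zero_phase"   # or "causal"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be ≥ 1")
        if not 0 < self.cutoff < self.fs / 2:
            raise ValueError("cutoff must lie in (0, fs/2)")
        if self.phase not in ("zero_phase", "causal"):
            raise ValueError("phase must be 'zero_phase' or 'causal'")


def butterworth_lowpass(ts: TimeSeries, spec: FilterSpec) -> TimeSeries:
    """Apply the Butterworth low-pass of *spec* to *ts*.

    Zero-phase mode runs the filter forward and backward (squared magnitude
    response, no lag) with reflected edge padding; causal mode is a single
    forward pass with the −3 dB point at the cutoff.
    """
    if abs(ts.fs - spec.fs) > 1e-6 * spec.fs:
        raise SamplingError(f"series sampled at {ts.fs:g} Hz but the filter "
                            f"was designed for {spec.fs:g} Hz")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=spec.fs,
                     output="sos")
    if spec.phase == "zero_phase":
        out = sps.sosfiltfilt(sos, ts.values)
    else:
        # start from the first sample's steady state to suppress the
        # turn-on transient of the causal pass
        zi = sps.sosfilt_zi(sos) * ts.values[0]
        out, _ = sps.sosfilt(sos, ts.values, zi=zi)
    return ts.copy_with(values=out)


def resample_to(ts: TimeSeries, target_fs: float,
                method: str = "linear") -> TimeSeries:
    """Linearly interpolate onto a uniform grid at *target_fs* Hz.

    The new grid starts at ``ts.t0`` and covers the original span; linear
    interpolation is exact on degree-1 signals and O(dt²) otherwise.
    """
    if method != "linear":
        raise ValueError("only linear resampling is provided")
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    dt = 1.0 / target_fs
    n = int(np.floor((ts.t_end - ts.t0) / dt + 1e-9)) + 1
    grid = ts.t0 + dt * np.arange(n)
    vals = np.interp(grid, ts.t, ts.values)
    return TimeSeries(t0=float(grid[0]), dt=dt, values=vals, unit=ts.unit,
                      meta=dict(ts.meta))


def _crop_to(ts: TimeSeries, t_lo: float, t_hi: float,
             target_fs: float) -> TimeSeries:
    dt = 1.0 / target_fs
    n = int(np.floor((t_hi - t_lo) / dt + 1e-9)) + 1
    grid = t_lo + dt * np.arange(n)
    return TimeSeries(t0=t_lo, dt=dt,
                      values=np.interp(grid, ts.t, ts.values),
                      unit=ts.unit, meta=dict(ts.meta))


def align_streams(displacement_ts: TimeSeries,
                  gauge_ts: TimeSeries,
                  dp_ts: TimeSeries,
                  lag_search: str = "off",
                  target_fs: float | None = None,
                  max_lag: float = 0.5):
    """Fuse the three streams onto one uniform grid (default: pressure rate).

    With ``lag_search="xcorr"`` an integer-sample lag between the
    displacement-derived kinematic flow and the pressure-drop signal is
    estimated from the cross-correlation peak and removed by shifting the
    displacement channel.  A lag beyond *max_lag* seconds triggers
    :class:`AlignmentWarning` (and is not applied).
    """
    if lag_search not in ("off", "xcorr"):
        raise ValueError("lag_search must be 'off' or 'xcorr'")
    fs = target_fs or gauge_ts.fs
    t_lo = max(displacement_ts.t0, gauge_ts.t0, dp_ts.t0)
    t_hi = min(displacement_ts.t_end, gauge_ts.t_end, dp_ts.t_end)
    if t_hi <= t_lo:
        raise AlignmentError("streams do not overlap in time")
    disp = _crop_to(displacement_ts, t_lo, t_hi, fs)
    gauge = _crop_to(gauge_ts, t_lo, t_hi, fs)
    dp = _crop_to(dp_ts, t_lo, t_hi, fs)

    if lag_search == "xcorr":
        # displacement is travel-from-start (positive either direction)
        # while ΔP flips sign with direction: correlate the magnitude
        # envelopes so the peak sits at the true lag for both strokes
        kin = np.abs(np.gradient(disp.values, disp.dt))
        a = kin - kin.mean()
        b = np.abs(dp.values)
        b = b - b.mean()
        xc = np.correlate(a, b, mode="full")
        lag = int(np.argmax(xc)) - (b.size - 1)   # disp lags dp by `lag`
        if abs(lag) * disp.dt > max_lag:
            warnings.warn(f"estimated lag {lag * disp.dt:.3f} s exceeds "
                          f"{max_lag} s; not applied", AlignmentWarning)
        elif lag != 0:
            shifted = displacement_ts.copy_with(t0=displacement_ts.t0
                                                - lag / fs)
            disp = _crop_to(shifted, t_lo, t_hi, fs)
    return disp, gauge, dp
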
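"""Adiabatic gas-compression correction for 3 L syringe strokes.

When a syringe is pushed fast against a flow resistance, the gas in the
barrel is compressed: the geometric swept volume S·x overstates what
actually left the barrel during the transient.  Treating the barrel gas as
an ideal gas undergoing adiabatic (P·V^γ = const) compression, the
instantaneous volume "stored" in compression is

    Vc = V_in · [((Psyr + Pb)/Pb)^(1/γ) − 1]            (form="paper")

with V_in the instantaneous in-cylinder volume (including dead space and
tubing), Psyr the in-cylinder gauge pressure and Pb barometric pressure.
An algebraically close variant referencing the pre-compression volume,

    Vc = V_in · [1 − (Pb/(Psyr + Pb))^(1/γ)]            (form="conservative")

agrees to first order in Psyr/Pb; at spirometric pressures (≲2 kPa) the two
differ by far less than sensor noise.  The corrected (ambient-referenced)
output volume is swept − Vc for a push stroke and swept + Vc for a pull
stroke (Vc < 0 during withdrawal, so the magnitude is reduced in both
cases); its time derivative is the *real output flow* against which the
pneumotachograph pressure drop is calibrated.
"""

from __future__ import annotations

import warnings

import numpy as np

from .exceptions import DirectionWarning, DomainError, SamplingError
from .params import GasParameters, SyringeGeometry
from .timeseries import TimeSeries

PUSH, PULL = "push", "pull"


def _check_direction(direction: str) -> str:
    if direction not in (PUSH, PULL):
        raise ValueError(f"direction must be '{PUSH}' or '{PULL}'")
    return direction


def swept_volume(displacement, geometry: SyringeGeometry):
    """Volume (L) swept by the piston after *displacement* cm of travel.

    Vectorized; raises :class:`DomainError` if any displacement lies
    outside [0, plunger_travel].
    """
    x = np.asarray(displacement, dtype=float)
    if np.any(x < 0) or np.any(x > geometry.plunger_travel * (1 + 1e-12)):
        raise DomainError("displacement outside [0, plunger_travel]")
    out = geometry.piston_area * x / 1000.0
    return float(out) if np.isscalar(displacement) else out


def infer_direction(displacement) -> str:
    """Stroke direction from the sign of net displacement travelled.

    Displacement is measured from the stroke start, so it grows in both
    directions; the caller-facing convention is that *push* expels gas and
    *pull* draws it in.  Used only as a fallback when no direction is
    stated; here net travel is always ≥ 0, so a stated direction wins.
    """
    x = np.asarray(displacement, dtype=float)
    return PUSH if x[-1] >= x[0] else PULL


def in_cylinder_volume(displacement_ts: TimeSeries,
                       geometry: SyringeGeometry,
                       direction: str) -> TimeSeries:
    """Instantaneous gas volume in the barrel (plus dead space), in L.

    For a push stroke the barrel starts full (nominal + dead volume) and
    empties as the piston advances; for a pull stroke it starts at the dead
    volume and fills.  Displacement x is distance travelled since stroke
    start in both cases.
    """
    _check_direction(direction)
    if displacement_ts.unit != "cm":
        raise ValueError("displacement must be in cm")
    x = displacement_ts.values
    net = x[-1] - x[0]
    if net < -1e-6:
        warnings.warn("displacement trend decreases; proceeding with the "
                      f"stated direction '{direction}'", DirectionWarning)
    sw = swept_volume(np.clip(x, 0.0, geometry.plunger_travel), geometry)
    if direction == PUSH:
        v = geometry.nominal_volume + geometry.dead_volume - sw
    else:
        v = geometry.dead_volume + sw
    return displacement_ts.copy_with(values=v, unit="L")


def compression_volume(v_in, gauge_pressure, gas: GasParameters,
                       form: str = "paper"):
    """Instantaneous compression volume Vc (L); sign follows the gauge.

    Parameters
    ----------
    v_in : float or array
        Instantaneous in-cylinder volume, L.
    gauge_pressure : float or array
        In-cylinder gauge pressure Psyr, Pa (negative during withdrawal).
    form : {"paper", "conservative"}
        Which algebraic variant to evaluate (see module docstring).
    """
    v = np.asarray(v_in, dtype=float)
    p = np.asarray(gauge_pressure, dtype=float)
    if np.any(v < 0):
        raise DomainError("in-cylinder volume must be non-negative")
    pb = gas.barometric_pressure
    if np.any(p + pb <= 0):
        raise DomainError("absolute pressure must be positive")
    ratio = (p + pb) / pb
    inv_gamma = 1.0 / gas.gamma
    if form == "paper":
        vc = v * (ratio ** inv_gamma - 1.0)
    elif form == "conservative":
        vc = v * (1.0 - ratio ** (-inv_gamma))
    else:
        raise ValueError(f"unknown form '{form}'")
    scalar = np.isscalar(v_in) and np.isscalar(gauge_pressure)
    return float(vc) if scalar else vc


def corrected_output_volume(displacement_ts: TimeSeries,
                            gauge_ts: TimeSeries,
                            geometry: SyringeGeometry,
                            gas: GasParameters,
                            direction: str | None = None,
                            form: str = "paper",
                            baseline_window: float = 0.2,
                            gauge_map: tuple[float, float] | None = None,
                            ) -> TimeSeries:
    """Compression-corrected cumulative output volume (L), zeroed at start.

    The first *baseline_window* seconds (plunger at rest) define both the
    gauge-pressure baseline and the displacement origin, absorbing sensor
    offset; set it to 0 to disable.  Displacement noise slightly outside
    [0, travel] is clipped before the swept-volume map.  The returned
    volume is signed positive for both stroke directions (volume expelled
    for push, drawn in for pull).

    *gauge_map* = (offset, slope): optional linear map applied to the
    gauge signal first, for setups where the in-cylinder pressure is
    inferred from a correlated upstream-tap measurement rather than
    measured at the barrel itself.
    """
    if direction is None:
        direction = infer_direction(displacement_ts.values)
    _check_direction(direction)
    if not displacement_ts.same_grid(gauge_ts, rtol=1e-6):
        raise SamplingError("displacement and gauge pressure must share a "
                            "common time grid; resample/align them first")
    x = displacement_ts.values.astype(float).copy()
    p = gauge_ts.values.astype(float).copy()
    if gauge_map is not None:
        p = gauge_map[0] + gauge_map[1] * p
    if baseline_window > 0:
        k = max(1, int(round(baseline_window / displacement_ts.dt)))
        k = min(k, x.size)
        x -= x[:k].mean()
        p -= p[:k].mean()
    x = np.clip(x, 0.0, geometry.plunger_travel)
    xs = displacement_ts.copy_with(values=x)
    v_in = in_cylinder_volume(xs, geometry, direction).values
    vc = compression_volume(v_in, p, gas, form=form)
    sw = swept_volume(x, geometry)
    if direction == PUSH:
        v_out = sw - vc
    else:
        # pull: Vc < 0 while the barrel gas is expanded, reducing the
        # volume actually drawn through the resistance
        v_out = sw + vc
    v_out = v_out - v_out[0]
    return displacement_ts.copy_with(values=v_out, unit="L")


def real_output_flow(v_out_ts: TimeSeries,
                     diff_scheme: str = "central") -> TimeSeries:
    """Real output flow (L/s): first derivative of the corrected volume.

    Central differences in the interior, one-sided at the ends, so the
    trapezoid integral of the result reproduces the net volume change to
    O(dt²).
    """
    if diff_scheme != "central":
        raise ValueError("only the central difference scheme is provided")
    if v_out_ts.n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    q = np.gradient(v_out_ts.values, v_out_ts.dt)
    return v_out_ts.copy_with(values=q, unit="L/s")
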
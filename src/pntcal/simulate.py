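"""Lumped-parameter simulation of a compressible 3 L syringe stroke.

The barrel gas is tracked as *ambient-equivalent content* C: the volume the
gas would occupy at barometric pressure after adiabatic re-expansion.  With
V_in(t) the geometric in-cylinder volume set by the plunger and the gas
adiabatic, the absolute barrel pressure is

    P(t) = Pb · (C(t) / V_in(t))^γ,

and the flow Q through the pneumotachograph solves the monotone resistance
law ΔP(Q) = k1·Q + k2·Q·|Q| = P − Pb in closed form.  Content is conserved:
dC/dt = −Q.  Near the ends of a stroke the in-cylinder volume approaches
the dead volume and the pressure relaxation becomes stiff (time constant
V/(γ·P·dQ/dΔP), tens of microseconds), so the scalar ODE is integrated
with a stiffness-switching LSODA solver at tight tolerance and the
channels are then sampled onto a uniform grid of step ``dt``.  Outflow
(push) gives Q > 0; withdrawal gives Q < 0.  In the zero-resistance limit
the gauge pressure vanishes and Q reduces to the kinematic flow S·v/1000.

A stroke consists of a rest pre-roll (used downstream to zero-reference the
gauge sensor), the sinusoidal plunger sweep, and a settle phase with the
plunger at rest while the barrel pressure equilibrates through the
resistance — so the cumulative output of a full push stroke converges to
the nominal 3 L.

``sample_sensors`` turns the ideal record into what the instrumentation
delivers: pressures resampled to 250 Hz and displacement to 60 Hz (the
video rate), additive Gaussian noise, and uniform ADC quantization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateModelError, DomainError, PhysicalityError
from .gas import PULL, PUSH
from .params import (DEFAULT_FULL_SCALE, DEFAULT_NOISE_SIGMA, GasParameters,
                     PistonMotion, ResistanceModel, SyringeGeometry)
from .timeseries import TimeSeries


# ---------------------------------------------------------------------------
# kinematics and resistance
# ---------------------------------------------------------------------------

def piston_velocity(t, motion: PistonMotion):
    """Plunger speed v(t) = 2πAf·sin(2πft) in cm/s, zero after the sweep."""
    t = np.asarray(t, dtype=float)
    w = 2.0 * math.pi * motion.frequency
    v = motion.amplitude * w * np.sin(w * t)
    v = np.where((t >= 0) & (t <= motion.duration), v, 0.0)
    return float(v) if v.ndim == 0 else v


def piston_displacement(t, motion: PistonMotion):
    """Plunger travel x(t) = A·(1 − cos 2πft) in cm, held after the sweep."""
    t = np.asarray(t, dtype=float)
    tc = np.clip(t, 0.0, motion.duration)
    w = 2.0 * math.pi * motion.frequency
    x = motion.amplitude * (1.0 - np.cos(w * tc))
    return float(x) if x.ndim == 0 else x


def pressure_drop(q, r: ResistanceModel):
    """ΔP(Q) = k1·Q + k2·Q·|Q| in Pa — odd and strictly monotone."""
    q = np.asarray(q, dtype=float)
    dp = r.k1 * q + r.k2 * q * np.abs(q)
    return float(dp) if dp.ndim == 0 else dp


def invert_pressure_drop(dp, r: ResistanceModel):
    """Unique flow Q (L/s) with pressure_drop(Q) = dp, in closed form."""
    if r.k1 == 0 and r.k2 == 0:
        raise DegenerateModelError("cannot invert with k1 = k2 = 0")
    dp = np.asarray(dp, dtype=float)
    if r.k2 == 0:
        q = dp / r.k1
    else:
        a = np.abs(dp)
        q = np.sign(dp) * (-r.k1 + np.sqrt(r.k1 * r.k1 + 4.0 * r.k2 * a)) \
            / (2.0 * r.k2)
    return float(q) if q.ndim == 0 else q


# ---------------------------------------------------------------------------
# stroke record
# ---------------------------------------------------------------------------

@dataclass
class StrokeRecord:
    """Ground-truth channels of one simulated stroke on a fine time grid.

    Flow and cumulative output are signed: positive for push (gas expelled)
    and negative for pull.  ``pnt_dp`` is the pressure drop across the
    pneumotachograph, which in this lumped single-resistance model equals
    the in-cylinder gauge pressure.
    """

    t: np.ndarray                 # s
    displacement: np.ndarray      # cm, travel since stroke start
    gauge: np.ndarray             # Pa, in-cylinder gauge pressure
    pnt_dp: np.ndarray            # Pa, pressure drop across the PNT
    flow: np.ndarray              # L/s, true output flow (signed)
    cumulative: np.ndarray        # L, ∫ flow dt (signed)
    direction: str
    motion: PistonMotion | None = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def peak_flow(self) -> float:
        """Peak |flow| in L/s."""
        return float(np.max(np.abs(self.flow)))

    @property
    def stroke_volume(self) -> float:
        """Net |volume| through the resistance over the whole record, L."""
        return float(abs(self.cumulative[-1]))

    def channel(self, name: str) -> TimeSeries:
        units = {"displacement": "cm", "gauge": "Pa", "pnt_dp": "Pa",
                 "flow": "L/s", "cumulative": "L"}
        return TimeSeries(t0=float(self.t[0]), dt=self.dt,
                          values=getattr(self, name), unit=units[name])


def simulate_stroke(geometry: SyringeGeometry,
                    gas: GasParameters,
                    resistance: ResistanceModel,
                    motion: PistonMotion,
                    dt: float = 1e-4,
                    direction: str = PUSH,
                    pre_roll: float = 0.3,
                    settle: float | str = "auto",
                    settle_tol: float = 0.5,
                    max_settle: float = 5.0) -> StrokeRecord:
    """Integrate one compressible stroke and return all channels.

    Parameters
    ----------
    dt : float
        Output grid step, s; must be ≤ 1e-3.  The solver itself is
        adaptive (LSODA, rtol 1e-9) and unaffected by *dt*.
    pre_roll : float
        Rest time before the sweep starts, s.
    settle : "auto" or float
        Post-sweep rest: "auto" integrates until |gauge| < *settle_tol* Pa
        (at most *max_settle* s); a float fixes the settle time.
    """
    from scipy.integrate import solve_ivp

    if direction not in (PUSH, PULL):
        raise ValueError("direction must be 'push' or 'pull'")
    if not 0 < dt <= 1e-3:
        raise DomainError("dt must lie in (0, 1e-3] s")
    motion.check_fits(geometry)

    pb = gas.barometric_pressure
    gamma = gas.gamma
    sign = 1.0 if direction == PUSH else -1.0
    s_l = geometry.piston_area / 1000.0      # L per cm of travel
    v_start = (geometry.nominal_volume + geometry.dead_volume
               if direction == PUSH else geometry.dead_volume)
    v_floor = 0.25 * geometry.dead_volume

    def v_in_at(t):
        x = piston_displacement(np.maximum(np.asarray(t) - pre_roll, 0.0),
                                motion)
        return v_start - sign * s_l * x

    def rhs(t, y):
        v = v_in_at(t)
        if np.any(v < v_floor):
            raise PhysicalityError(
                "in-cylinder volume collapsed below a quarter of the dead "
                "volume; check geometry and motion amplitude")
        p = pb * (y[0] / v) ** gamma
        return [-invert_pressure_drop(p - pb, resistance)]

    t_sweep_end = pre_roll + motion.duration
    c0 = v_start
    # pre-roll is exactly static (gauge 0, no flow); start the solver at
    # the sweep and keep the rest phase analytic
    sol_sweep = solve_ivp(rhs, (pre_roll, t_sweep_end), [c0],
                          method="LSODA", rtol=1e-9,
                          atol=1e-12 * v_start, dense_output=True)
    if not sol_sweep.success:      # pragma: no cover - defensive
        raise PhysicalityError(f"stroke integration failed: "
                               f"{sol_sweep.message}")
    c_sweep_end = float(sol_sweep.y[0, -1])

    settle_len = max_settle if settle == "auto" else float(settle)
    if settle == "auto":
        g_end = pb * ((c_sweep_end / v_in_at(t_sweep_end)) ** gamma - 1.0)
        if abs(g_end) < settle_tol:     # already equilibrated at sweep end
            settle_len = min(0.1, max_settle)
    sol_settle = None
    t_end = t_sweep_end
    if settle_len > 0:
        def equilibrated(t, y):
            v = v_in_at(t)
            p_gauge = pb * ((y[0] / v) ** gamma - 1.0)
            return abs(p_gauge) - settle_tol
        equilibrated.terminal = settle == "auto"
        sol_settle = solve_ivp(rhs, (t_sweep_end, t_sweep_end + settle_len),
                               [c_sweep_end], method="LSODA", rtol=1e-9,
                               atol=1e-12 * v_start, dense_output=True,
                               events=equilibrated)
        if not sol_settle.success:     # pragma: no cover - defensive
            raise PhysicalityError(f"settle integration failed: "
                                   f"{sol_settle.message}")
        t_end = float(sol_settle.t[-1])

    n = int(math.floor(t_end / dt + 1e-9)) + 1
    t_arr = dt * np.arange(n)
    c_arr = np.full(n, c0)
    in_sweep = (t_arr >= pre_roll) & (t_arr <= t_sweep_end)
    c_arr[in_sweep] = sol_sweep.sol(t_arr[in_sweep])[0]
    if sol_settle is not None:
        in_settle = t_arr > t_sweep_end
        c_arr[in_settle] = sol_settle.sol(t_arr[in_settle])[0]
    v_arr = v_in_at(t_arr)
    g_arr = pb * ((c_arr / v_arr) ** gamma - 1.0)
    q_arr = invert_pressure_drop(g_arr, resistance)
    xs = np.where(t_arr >= pre_roll,
                  piston_displacement(np.maximum(t_arr - pre_roll, 0.0),
                                      motion), 0.0)
    c = float(c_arr[-1])
    steps = np.diff(t_arr)
    cum = np.concatenate([[0.0],
                          np.cumsum(0.5 * steps * (q_arr[1:] + q_arr[:-1]))])
    return StrokeRecord(
        t=t_arr, displacement=xs, gauge=g_arr,
        pnt_dp=pressure_drop(q_arr, resistance), flow=q_arr, cumulative=cum,
        direction=direction, motion=motion,
        meta={"dt": dt, "pre_roll": pre_roll,
              "content_start": c0, "content_end": c})


# ---------------------------------------------------------------------------
# sensor sampling
# ---------------------------------------------------------------------------

@dataclass
class SensorTraces:
    """Noisy, quantized sensor view of one stroke.

    Pressure channels at the ADC rate (250 Hz), displacement at the video
    frame rate (60 Hz).  Deterministic under a fixed seed.
    """

    gauge: TimeSeries
    pnt_dp: TimeSeries
    displacement: TimeSeries
    direction: str
    noise_sigma: dict
    bits: int | None
    seed: int


def _quantize(x: np.ndarray, lo: float, hi: float, bits: int | None):
    if bits is None:
        return x
    lsb = (hi - lo) / (2 ** bits)
    return lo + np.round((np.clip(x, lo, hi) - lo) / lsb) * lsb


def sample_sensors(rec: StrokeRecord,
                   noise_sigma: dict | None = None,
                   bits: int | None = 12,
                   seed: int = 0,
                   pressure_fs: float = 250.0,
                   video_fps: float = 60.0,
                   full_scale: dict | None = None) -> SensorTraces:
    """Resample, add Gaussian noise and quantize the stroke channels."""
    sigma = dict(DEFAULT_NOISE_SIGMA)
    sigma.update(noise_sigma or {})
    if any(v < 0 for v in sigma.values()):
        raise ValueError("noise sigmas must be non-negative")
    if bits is not None and bits < 8:
        warnings.warn("fewer than 8 ADC bits: quantization will dominate "
                      "the pressure channels")
    fs_rng = dict(DEFAULT_FULL_SCALE)
    fs_rng.update(full_scale or {})
    rng = np.random.default_rng(seed)

    def make(name: str, rate: float) -> TimeSeries:
        dt = 1.0 / rate
        n = int(math.floor((rec.t[-1] - rec.t[0]) / dt)) + 1
        grid = rec.t[0] + dt * np.arange(n)
        clean = np.interp(grid, rec.t, getattr(rec, name))
        noisy = clean + rng.normal(0.0, sigma[name], size=n) \
            if sigma[name] > 0 else clean.copy()
        lo, hi = fs_rng[name]
        unit = {"gauge": "Pa", "pnt_dp": "Pa", "displacement": "cm"}[name]
        return TimeSeries(t0=float(grid[0]), dt=dt,
                          values=_quantize(noisy, lo, hi, bits), unit=unit)

    return SensorTraces(gauge=make("gauge", pressure_fs),
                        pnt_dp=make("pnt_dp", pressure_fs),
                        displacement=make("displacement", video_fps),
                        direction=rec.direction,
                        noise_sigma=sigma, bits=bits, seed=seed)


# ---------------------------------------------------------------------------
# validation suite
# ---------------------------------------------------------------------------

def solve_motion_for_peak_flow(target: float,
                               geometry: SyringeGeometry,
                               gas: GasParameters,
                               resistance: ResistanceModel,
                               direction: str = PUSH,
                               rtol: float = 0.005,
                               solver_dt: float = 1e-3,
                               max_iter: int = 8) -> PistonMotion:
    """Full-stroke motion whose true peak |flow| matches *target* (L/s).

    Starts from the incompressible kinematic guess 2πAf·S/1000 = target and
    refines the frequency by fixed-point iteration against coarse
    simulations until the simulated peak is within *rtol* of the target.
    """
    if target <= 0:
        raise DomainError("target peak flow must be positive")
    amp = geometry.plunger_travel / 2.0
    f = target * 1000.0 / (geometry.piston_area * 2.0 * math.pi * amp)
    for _ in range(max_iter):
        motion = PistonMotion(amplitude=amp, frequency=f)
        rec = simulate_stroke(geometry, gas, resistance, motion,
                              dt=solver_dt, direction=direction,
                              pre_roll=0.1, settle=0.0)
        peak = rec.peak_flow
        if abs(peak - target) <= rtol * target:
            return motion
        f *= target / peak
    return PistonMotion(amplitude=amp, frequency=f)


def generate_validation_suite(n: int,
                              peak_flow_range: tuple[float, float],
                              geometry: SyringeGeometry,
                              gas: GasParameters,
                              resistance: ResistanceModel,
                              seed: int = 0,
                              dt: float = 1e-4) -> list[StrokeRecord]:
    """*n* full strokes alternating push/pull with peak flows tiling a range.

    Targets are ceil(n/2) levels spaced linearly over *peak_flow_range*;
    each level contributes a push and a pull stroke (push first).  The
    suite is deterministic; *seed* is recorded in each stroke's metadata so
    downstream sensor sampling can derive per-stroke noise seeds.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    lo, hi = peak_flow_range
    if not 0 < lo <= hi:
        raise DomainError("peak flow range must be positive and ordered")
    n_levels = (n + 1) // 2
    targets = np.linspace(lo, hi, n_levels) if n_levels > 1 \
        else np.array([0.5 * (lo + hi)])
    records: list[StrokeRecord] = []
    for i in range(n):
        target = float(targets[i // 2])
        direction = PUSH if i % 2 == 0 else PULL
        motion = solve_motion_for_peak_flow(target, geometry, gas,
                                            resistance, direction)
        rec = simulate_stroke(geometry, gas, resistance, motion,
                              dt=dt, direction=direction)
        rec.meta.update(target_peak_flow=target, suite_seed=seed, index=i)
        records.append(rec)
    return records
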
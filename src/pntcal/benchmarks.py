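"""Desk-scale validation studies of the calibration system.

Three self-contained studies quantify the pipeline against the bounds a
spirometry calibration must satisfy:

* :func:`ats_validation_study` — end-to-end calibration on a push/pull
  suite tiling 1–14 L/s with default sensor noise, validated on held-out
  waveforms against the ATS flow-accuracy rule (±5% of reading or
  ±0.200 L/s) with Bland–Altman agreement.
* :func:`tracking_volume_study` — stroke volumes recovered by the
  mean-shift tracker from rendered marker videos of full 3 L strokes.
* :func:`fit_quality_study` — R² of the polynomial calibration fit over
  the 14 constant flow levels 1..14 L/s with mild multiplicative sensor
  noise.

Each study derives all randomness from a single seed and reports plain
dictionaries, so results are reproducible and serializable.
"""

from __future__ import annotations

import numpy as np

from . import calibration as cal
from .params import Config, PistonMotion
from .pipeline import derive_seed, simulate_sensor_suite
from .tracking import TrackWindow, render_frames, track, \
    trajectory_to_displacement


def ats_validation_study(seed: int = 0, n_calibration: int = 20,
                         n_validation: int = 20,
                         peak_flow_range: tuple[float, float] = (1.0, 14.0),
                         config: Config | None = None) -> dict:
    """Calibrate end-to-end and validate held-out peak flows.

    Calibration and validation waveform suites both tile
    *peak_flow_range* with alternating push/pull full strokes; held-out
    waveforms carry independent sensor-noise realizations.  Returns the
    per-waveform report plus the maximum relative peak-flow error over the
    percentage-dominated subset (true peak > 4 L/s, where the ATS 5%
    term exceeds the 0.200 L/s floor).
    """
    config = config or Config(seed=seed)
    config.seed = seed
    _, cal_traces = simulate_sensor_suite(
        config, n_calibration, peak_flow_range, seed_stream=1)
    val_records, val_traces = simulate_sensor_suite(
        config, n_validation, peak_flow_range, seed_stream=2)
    validation = [(tr, rec.peak_flow)
                  for tr, rec in zip(val_traces, val_records)]
    curve, report = cal.end_to_end_calibrate(cal_traces, config,
                                             validation=validation)
    return {
        "curve": curve,
        "report": report,
        "n_waveforms": n_validation,
        "all_ats_pass": report.all_pass,
        "max_rel_error_pct": report.extras["max_rel_error_pct"],
        "max_rel_error_pct_dominated":
            report.extras.get("max_rel_error_pct_dominated"),
        "bias_lps": report.bias,
        "r2": curve.r2,
    }


def tracking_volume_study(seed: int = 0, n_videos: int = 20,
                          frequency_range: tuple[float, float] = (0.12, 0.5),
                          config: Config | None = None) -> dict:
    """Track full-stroke marker videos and measure stroke-volume errors.

    Renders *n_videos* videos (half push, half pull by image direction) of
    a red marker sweeping the full 37.5 cm plunger travel at speeds tiling
    *frequency_range*, with default pixel noise.  Each trajectory is
    converted to displacement via the renderer's pixel scale and to volume
    via the piston area; errors are percentages of the 3 L nominal volume.
    """
    config = config or Config(seed=seed)
    config.seed = seed
    geom = config.geometry
    n_levels = (n_videos + 1) // 2
    freqs = np.linspace(*frequency_range, n_levels) if n_levels > 1 \
        else [float(np.mean(frequency_range))]
    errors, volumes = [], []
    for i in range(n_videos):
        f = float(freqs[i // 2])
        sign = 1 if i % 2 == 0 else -1
        motion = PistonMotion(amplitude=geom.plunger_travel / 2.0,
                              frequency=f)
        frames = render_frames(motion, fps=config.video_fps,
                               direction_sign=sign,
                               seed=derive_seed(seed, 500 + i))
        init = TrackWindow(center=(frames.meta["true_row"],
                                   frames.meta["true_cols"][0]))
        traj = track(frames, init)
        disp = trajectory_to_displacement(traj, frames.px_per_cm)
        stroke_cm = float(np.max(np.abs(disp.values)))
        vol = stroke_cm * geom.piston_area / 1000.0
        volumes.append(vol)
        errors.append(100.0 * abs(vol - geom.nominal_volume)
                      / geom.nominal_volume)
    return {
        "n_videos": n_videos,
        "volumes_l": volumes,
        "errors_pct_of_nominal": errors,
        "max_error_pct": float(max(errors)),
        "mean_error_pct": float(np.mean(errors)),
    }


def fit_quality_study(seed: int = 0, n_replicates: int = 10,
                      noise_fraction: float = 0.005,
                      config: Config | None = None) -> dict:
    """R² of the calibration polynomial over 14 constant flow levels.

    For Q = 1..14 L/s the pressure drop follows the resistance law
    ΔP = k1·Q + k2·Q², perturbed by multiplicative Gaussian noise
    (*noise_fraction*, default 0.5%) across *n_replicates* repetitions per
    level; an order-3 polynomial Q(ΔP) is fitted by least squares.
    """
    config = config or Config(seed=seed)
    r = config.resistance
    rng = np.random.default_rng(derive_seed(seed, 42))
    q = np.repeat(np.arange(1.0, 15.0), n_replicates)
    dp = (r.k1 * q + r.k2 * q * q) \
        * (1.0 + rng.normal(0.0, noise_fraction, q.size))
    ds = cal.CalibrationDataset(
        dp=dp, q=q, stroke_id=np.repeat(np.arange(14), n_replicates),
        direction=np.full(q.size, "push", dtype=object))
    curve = cal.fit_calibration(ds, order=config.poly_order)
    return {"r2": float(curve.r2), "n_levels": 14,
            "n_replicates": n_replicates, "curve": curve}
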
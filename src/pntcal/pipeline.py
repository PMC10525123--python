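"""Pipeline stages behind the CLI: simulate → track → correct → calibrate →
validate, each writing plain-text artifacts into an output directory.

Every stage derives its random seeds from ``config.seed`` alone, so a rerun
with the same configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import calibration as cal
from . import gas, signals, simulate, tracking
from .params import Config, PistonMotion
from .timeseries import read_timeseries, write_timeseries

log = logging.getLogger("pntcal")

#: peak-flow range (L/s) exercised by the quick CLI stages
DEMO_RANGE = (2.0, 10.0)


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic per-stream seed below 2^31 derived from the run seed."""
    return (seed * 100_003 + 7919 * stream + 1) % (2**31 - 1)


def _log_config(config: Config) -> None:
    log.info("run configuration: %s", json.dumps(config.to_dict(),
                                                 sort_keys=True))


def simulate_sensor_suite(config: Config, n: int,
                          peak_range: tuple[float, float],
                          seed_stream: int = 0):
    """Simulate *n* strokes tiling *peak_range* and sample their sensors."""
    records = simulate.generate_validation_suite(
        n, peak_range, config.geometry, config.gas, config.resistance,
        seed=config.seed, dt=config.sim_dt)
    traces = [simulate.sample_sensors(
        rec, noise_sigma=config.noise_sigma, bits=config.adc_bits,
        seed=derive_seed(config.seed, seed_stream * 1000 + i),
        pressure_fs=config.pressure_fs, video_fps=config.video_fps)
        for i, rec in enumerate(records)]
    return records, traces


def run_simulate(config: Config, out_dir, n: int = 8,
                 peak_range=DEMO_RANGE) -> dict:
    """Write per-stroke sensor CSVs plus ground truth and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_config(config)
    records, traces = simulate_sensor_suite(config, n, peak_range)
    manifest = {"n_strokes": n, "seed": config.seed, "strokes": []}
    for i, (rec, tr) in enumerate(zip(records, traces)):
        stem = f"stroke{i:02d}"
        write_timeseries(tr.displacement, out / f"{stem}_displacement.csv",
                         name="displacement")
        write_timeseries(tr.gauge, out / f"{stem}_gauge.csv", name="gauge")
        write_timeseries(tr.pnt_dp, out / f"{stem}_pnt_dp.csv", name="dp")
        write_timeseries(rec.channel("flow"), out / f"{stem}_true_flow.csv",
                         name="flow")
        manifest["strokes"].append(
            {"stem": stem, "direction": rec.direction,
             "target_peak_flow_lps": rec.meta.get("target_peak_flow"),
             "true_peak_flow_lps": rec.peak_flow,
             "true_stroke_volume_l": rec.stroke_volume})
    (out / "suite.json").write_text(json.dumps(manifest, indent=1,
                                               sort_keys=True))
    log.info("wrote %d simulated strokes to %s", n, out)
    return manifest


def run_track(config: Config, out_dir, frequency: float = 0.25) -> dict:
    """Render one full-stroke marker video, track it, write the trajectory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_config(config)
    motion = PistonMotion(amplitude=config.geometry.plunger_travel / 2.0,
                          frequency=frequency)
    frames = tracking.render_frames(motion, fps=config.video_fps,
                                    seed=derive_seed(config.seed, 77))
    r0 = frames.meta["true_row"]
    c0 = frames.meta["true_cols"][0]
    traj = tracking.track(frames, tracking.TrackWindow(center=(r0, c0)))
    disp = tracking.trajectory_to_displacement(traj, frames.px_per_cm)
    write_timeseries(disp, out / "tracked_displacement.csv",
                     name="displacement")
    np.savetxt(out / "trajectory_px.csv", traj.centers, delimiter=",",
               header="row_px,col_px", comments="")
    stroke_cm = float(np.max(np.abs(disp.values)))
    volume = stroke_cm * config.geometry.piston_area / 1000.0
    result = {"stroke_displacement_cm": stroke_cm,
              "stroke_volume_l": volume,
              "volume_error_pct_of_3l":
                  100.0 * abs(volume - config.geometry.nominal_volume)
                  / config.geometry.nominal_volume,
              "n_frames": frames.n}
    (out / "tracking_result.json").write_text(
        json.dumps(result, indent=1, sort_keys=True))
    log.info("tracked stroke volume %.4f L", volume)
    return result


def run_correct(config: Config, out_dir) -> list:
    """Apply the gas-compression correction to strokes under *out_dir*.

    Expects the artifacts of a previous ``simulate`` run (suite.json plus
    per-stroke displacement and gauge CSVs); writes corrected volume and
    real-output-flow CSVs next to them.
    """
    out = Path(out_dir)
    suite_path = out / "suite.json"
    if not suite_path.exists():
        raise FileNotFoundError(
            f"{suite_path} not found — run --mode simulate into this "
            "directory first")
    _log_config(config)
    manifest = json.loads(suite_path.read_text())
    results = []
    spec = signals.FilterSpec(fs=config.pressure_fs,
                              order=config.filter_order,
                              cutoff=config.filter_cutoff)
    for entry in manifest["strokes"]:
        stem = entry["stem"]
        disp = read_timeseries(out / f"{stem}_displacement.csv", "cm")
        gauge = read_timeseries(out / f"{stem}_gauge.csv", "Pa")
        disp_r, gauge_r, _ = signals.align_streams(disp, gauge, gauge)
        disp_f = signals.butterworth_lowpass(disp_r, spec)
        gauge_f = signals.butterworth_lowpass(gauge_r, spec)
        v_out = gas.corrected_output_volume(disp_f, gauge_f,
                                            config.geometry, config.gas,
                                            direction=entry["direction"])
        flow = gas.real_output_flow(v_out)
        write_timeseries(v_out, out / f"{stem}_corrected_volume.csv",
                         name="volume")
        write_timeseries(flow, out / f"{stem}_real_flow.csv", name="flow")
        results.append({"stem": stem,
                        "corrected_volume_l": float(v_out.values[-1])})
        log.info("%s: corrected output volume %.4f L", stem,
                 v_out.values[-1])
    return results


def run_calibrate(config: Config, out_dir, n_cal: int = 8,
                  peak_range=DEMO_RANGE):
    """Simulate a calibration suite, fit the curve, write it as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_config(config)
    _, traces = simulate_sensor_suite(config, n_cal, peak_range,
                                      seed_stream=1)
    curve, _ = cal.end_to_end_calibrate(traces, config)
    curve.to_json(out / "calibration_curve.json")
    log.info("calibration fit: order %d, R² = %.6f", curve.order, curve.r2)
    return curve


def run_validate(config: Config, out_dir, n_cal: int = 8, n_val: int = 6,
                 peak_range=DEMO_RANGE):
    """Calibrate, then validate held-out waveforms; write the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _log_config(config)
    _, cal_traces = simulate_sensor_suite(config, n_cal, peak_range,
                                          seed_stream=1)
    val_records, val_traces = simulate_sensor_suite(config, n_val,
                                                    peak_range,
                                                    seed_stream=2)
    validation = [(tr, rec.peak_flow)
                  for tr, rec in zip(val_traces, val_records)]
    curve, report = cal.end_to_end_calibrate(cal_traces, config,
                                             validation=validation)
    curve.to_json(out / "calibration_curve.json")
    report.per_waveform.to_csv(out / "validation_report.csv", index=False)
    summary = (f"polynomial order {curve.order}, R² = {curve.r2:.6f}\n"
               + report.summary() + "\n")
    (out / "validation_summary.txt").write_text(summary)
    log.info("validation: %s", report.summary().replace("\n", " | "))
    return curve, report


def run_demo(config: Config, out_dir):
    """End-to-end demonstration: validate + one tracked video stroke."""
    curve, report = run_validate(config, out_dir)
    track_result = run_track(config, out_dir)
    return curve, report, track_result


MODES = {"simulate": run_simulate, "track": run_track,
         "correct": run_correct, "calibrate": run_calibrate,
         "validate": run_validate, "demo": run_demo}


def run_pipeline(config: Config, mode: str, out_dir) -> int:
    """Dispatch one pipeline mode; returns a process exit status."""
    if mode not in MODES:
        raise ValueError(f"unknown mode '{mode}'; choose from "
                         f"{sorted(MODES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    MODES[mode](config, out_dir)
    return 0
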
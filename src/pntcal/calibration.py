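"""Polynomial pressure-drop → flow calibration and its validation.

The calibration curve maps the pneumotachograph pressure drop ΔP (Pa) to
flow Q (L/s) with a least-squares polynomial.  Because the resistance law
is odd (ΔP and Q share sign) the default fit pools push and pull samples
onto one odd curve: the polynomial is fitted on (|ΔP|, sign(ΔP)·Q) and
evaluated as sign(ΔP)·p(|ΔP|).  A raw signed polynomial and per-direction
fits remain available, but a low-order polynomial forced through the
sign-change kink at ΔP = 0 is markedly less accurate at the range ends.

Validation follows spirometry practice: per-waveform peak-flow errors are
judged against the ATS bound — within ±5% of reading or ±0.200 L/s,
whichever is larger — and agreement between measured and reference peak
flows is summarized by Bland–Altman bias and limits of agreement
(bias ± 1.96·SD).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CoverageWarning, FitError
from .gas import PUSH, corrected_output_volume, real_output_flow
from .params import Config
from .signals import FilterSpec, align_streams, butterworth_lowpass
from .timeseries import TimeSeries

#: ATS flow-accuracy rule: ±5% of reading or ±0.200 L/s, whichever is larger
ATS_RELATIVE = 0.05
ATS_ABSOLUTE = 0.200


# ---------------------------------------------------------------------------
# dataset and curve
# ---------------------------------------------------------------------------

@dataclass
class CalibrationDataset:
    """Pooled (ΔP, Q) pairs with per-sample stroke id and direction."""

    dp: np.ndarray              # Pa
    q: np.ndarray               # L/s, signed
    stroke_id: np.ndarray
    direction: np.ndarray       # "push" / "pull" per sample

    def __post_init__(self) -> None:
        self.dp = np.asarray(self.dp, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.stroke_id = np.asarray(self.stroke_id)
        self.direction = np.asarray(self.direction)
        n = self.dp.size
        if not (self.q.size == n and self.stroke_id.size == n
                and self.direction.size == n):
            raise ValueError("all dataset columns must share one length")
        if n == 0 or not (np.isfinite(self.dp).all()
                          and np.isfinite(self.q).all()):
            raise ValueError("dataset must be non-empty and finite")

    @classmethod
    def from_strokes(cls, pairs) -> "CalibrationDataset":
        """Build from an iterable of (dp_array, q_array, direction) triples."""
        dps, qs, sids, dirs = [], [], [], []
        for i, (dp, q, direction) in enumerate(pairs):
            dp = np.asarray(dp, dtype=float)
            dps.append(dp)
            qs.append(np.asarray(q, dtype=float))
            sids.append(np.full(dp.size, i))
            dirs.append(np.full(dp.size, direction, dtype=object))
        return cls(dp=np.concatenate(dps), q=np.concatenate(qs),
                   stroke_id=np.concatenate(sids),
                   direction=np.concatenate(dirs))


@dataclass
class CalibrationCurve:
    """Fitted ΔP → Q polynomial with diagnostics.

    ``coef`` is ordered low → high degree.  With ``symmetry="odd"`` the
    polynomial acts on |ΔP| and the sign of ΔP is restored afterwards.
    """

    coef: np.ndarray
    order: int
    symmetry: str = "odd"       # or "none"
    r2: float = float("nan")
    resid_rms: float = float("nan")
    dp_range: tuple[float, float] = (float("nan"), float("nan"))

    def __call__(self, dp):
        dp = np.asarray(dp, dtype=float)
        if self.symmetry == "odd":
            out = np.sign(dp) * np.polynomial.polynomial.polyval(
                np.abs(dp), self.coef)
        else:
            out = np.polynomial.polynomial.polyval(dp, self.coef)
        return float(out) if out.ndim == 0 else out

    def in_range(self, dp) -> np.ndarray:
        dp = np.asarray(dp, dtype=float)
        return (dp >= self.dp_range[0]) & (dp <= self.dp_range[1])

    def to_json(self, path=None) -> str:
        d = {"coefficients_low_to_high": list(map(float, self.coef)),
             "order": int(self.order), "symmetry": self.symmetry,
             "r2": float(self.r2), "residual_rms": float(self.resid_rms),
             "dp_range_pa": [float(self.dp_range[0]),
                             float(self.dp_range[1])]}
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(coef=np.asarray(d["coefficients_low_to_high"]),
                   order=d["order"], symmetry=d["symmetry"], r2=d["r2"],
                   resid_rms=d["residual_rms"],
                   dp_range=tuple(d["dp_range_pa"]))


def fit_calibration(ds: CalibrationDataset, order: int = 3,
                    weighting: str = "none", symmetry: str = "odd",
                    zero_intercept: bool = False) -> CalibrationCurve:
    """Least-squares polynomial Q(ΔP) of the given order (1–5).

    ``weighting="by_density"`` down-weights densely sampled pressure bins
    so slow strokes (many near-zero samples) do not dominate the fit.
    """
    if not 1 <= order <= 5:
        raise ValueError("order must be in [1, 5]")
    if symmetry not in ("odd", "none"):
        raise ValueError("symmetry must be 'odd' or 'none'")
    if weighting not in ("none", "by_density"):
        raise ValueError("weighting must be 'none' or 'by_density'")
    if symmetry == "odd":
        x = np.abs(ds.dp)
        y = np.sign(ds.dp) * ds.q
        # ΔP = 0 carries no sign; Q there is ~0 and contributes either way
        y = np.where(ds.dp == 0, ds.q, y)
    else:
        x, y = ds.dp, ds.q
    if np.unique(x).size < order + 1:
        raise FitError(f"only {np.unique(x).size} distinct pressure values; "
                       f"an order-{order} fit needs {order + 1}")
    if weighting == "by_density":
        counts, edges = np.histogram(x, bins=20)
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, 19)
        w = 1.0 / np.maximum(counts[idx], 1)
    else:
        w = np.ones_like(x)
    powers = np.arange(1 if zero_intercept else 0, order + 1)
    design = x[:, None] ** powers[None, :]
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    coef = np.zeros(order + 1)
    coef[powers] = beta
    curve = CalibrationCurve(coef=coef, order=order, symmetry=symmetry,
                             dp_range=(float(ds.dp.min()),
                                       float(ds.dp.max())))
    pred = curve(ds.dp)
    ss_res = float(np.sum((ds.q - pred) ** 2))
    ss_tot = float(np.sum((ds.q - ds.q.mean()) ** 2))
    curve.r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    curve.resid_rms = float(np.sqrt(ss_res / ds.q.size))
    return curve


def apply_calibration(curve: CalibrationCurve,
                      dp_ts: TimeSeries) -> TimeSeries:
    """Evaluate the curve on a ΔP trace; flags (never clips) extrapolation."""
    q = curve(dp_ts.values)
    out = dp_ts.copy_with(values=q, unit="L/s")
    outside = ~curve.in_range(dp_ts.values)
    out.meta["extrapolation"] = bool(outside.any())
    out.meta["n_extrapolated"] = int(outside.sum())
    return out


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Bland–Altman agreement plus per-waveform ATS accuracy results."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    diffs: np.ndarray
    means: np.ndarray
    errors: np.ndarray | None = None       # measured − reference, per pair
    tolerances: np.ndarray | None = None   # ATS tolerance per pair
    ats_pass: np.ndarray | None = None
    per_waveform: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return bool(self.ats_pass is not None and self.ats_pass.all())

    def summary(self) -> str:
        lines = [f"bias             {self.bias:+.4f} L/s",
                 f"limits of agreement  [{self.loa_low:+.4f}, "
                 f"{self.loa_high:+.4f}] L/s (bias ± 1.96·SD)"]
        if self.ats_pass is not None:
            lines.append(f"ATS rule (±5% of reading or ±0.200 L/s): "
                         f"{int(self.ats_pass.sum())}/{self.ats_pass.size} "
                         "waveforms pass")
        return "\n".join(lines)


def ats_accuracy_check(measured_peaks, reference_peaks):
    """Per-pair ATS accuracy: tolerance = max(5% of |reference|, 0.200 L/s).

    Peak flows are compared on magnitudes so pull (negative-flow) waveforms
    are judged identically to push.  Returns (errors, tolerances, passes).
    """
    m = np.abs(np.asarray(measured_peaks, dtype=float))
    r = np.abs(np.asarray(reference_peaks, dtype=float))
    if m.shape != r.shape:
        raise ValueError("measured and reference arrays must match in length")
    tol = np.maximum(ATS_RELATIVE * r, ATS_ABSOLUTE)
    err = m - r
    return err, tol, np.abs(err) <= tol


def bland_altman(measured, reference) -> AgreementReport:
    """Bland–Altman agreement: bias, SD (n−1) and bias ± 1.96·SD limits."""
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape:
        raise ValueError("measured and reference arrays must match in length")
    if m.size < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    d = m - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(bias=bias, sd=sd,
                           loa_low=bias - 1.96 * sd,
                           loa_high=bias + 1.96 * sd,
                           diffs=d, means=0.5 * (m + r))


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def process_stroke(traces, config: Config,
                   lag_search: str = "off"):
    """Align → filter → correct → differentiate one stroke's sensor traces.

    Returns (dp, q) arrays on the pressure grid: the filtered
    pneumotachograph pressure drop and the signed real output flow derived
    from displacement plus gauge pressure.
    """
    spec = FilterSpec(fs=config.pressure_fs, order=config.filter_order,
                      cutoff=config.filter_cutoff, phase="zero_phase")
    disp, gauge, dp = align_streams(traces.displacement, traces.gauge,
                                    traces.pnt_dp, lag_search=lag_search)
    disp = butterworth_lowpass(disp, spec)
    gauge = butterworth_lowpass(gauge, spec)
    dp = butterworth_lowpass(dp, spec)
    v_out = corrected_output_volume(disp, gauge, config.geometry,
                                    config.gas,
                                    direction=traces.direction)
    q = real_output_flow(v_out).values
    sign = 1.0 if traces.direction == PUSH else -1.0
    return dp.values, sign * q


def measure_peak_flow(curve: CalibrationCurve, traces,
                      config: Config) -> float:
    """Peak |flow| of a waveform via the calibration curve (L/s)."""
    spec = FilterSpec(fs=config.pressure_fs, order=config.filter_order,
                      cutoff=config.filter_cutoff, phase="zero_phase")
    dp = butterworth_lowpass(
        traces.pnt_dp if abs(traces.pnt_dp.fs - config.pressure_fs) < 1e-6
        else traces.pnt_dp, spec)
    flow = apply_calibration(curve, dp)
    return float(np.max(np.abs(flow.values)))


def end_to_end_calibrate(calibration_traces: list,
                         config: Config,
                         validation: list | None = None,
                         weighting: str = "none"):
    """Full pipeline: pool calibration strokes, fit, validate held-out peaks.

    Parameters
    ----------
    calibration_traces : list of SensorTraces
        Strokes used to build the (ΔP, Q) dataset.
    validation : list of (SensorTraces, float), optional
        Held-out waveforms with their reference peak flows (L/s).  If
        given, the returned report carries ATS and Bland–Altman results.

    Returns
    -------
    (CalibrationCurve, AgreementReport or None)
    """
    pairs = []
    for tr in calibration_traces:
        dp, q = process_stroke(tr, config)
        pairs.append((dp, q, tr.direction))
    ds = CalibrationDataset.from_strokes(pairs)
    curve = fit_calibration(ds, order=config.poly_order, weighting=weighting)
    if validation is None:
        return curve, None
    measured, reference, directions = [], [], []
    for tr, ref_peak in validation:
        measured.append(measure_peak_flow(curve, tr, config))
        reference.append(abs(ref_peak))
        directions.append(tr.direction)
    measured = np.asarray(measured)
    reference = np.asarray(reference)
    needed = np.max(reference)
    covered = np.max(np.abs(ds.dp))
    fitted_peak = abs(curve(covered))
    if fitted_peak < 0.95 * needed:
        warnings.warn(
            f"calibration data reach only ~{fitted_peak:.1f} L/s but "
            f"validation requests {needed:.1f} L/s", CoverageWarning)
    err, tol, ok = ats_accuracy_check(measured, reference)
    report = bland_altman(measured, reference)
    report.errors, report.tolerances, report.ats_pass = err, tol, ok
    report.per_waveform = pd.DataFrame(
        {"direction": directions, "reference_peak_lps": reference,
         "measured_peak_lps": measured, "error_lps": err,
         "tolerance_lps": tol, "ats_pass": ok})
    rel = np.abs(err) / reference
    report.extras["max_rel_error_pct"] = float(100 * rel.max())
    pct_dom = reference > ATS_ABSOLUTE / ATS_RELATIVE   # 4 L/s crossover
    if pct_dom.any():
        report.extras["max_rel_error_pct_dominated"] = \
            float(100 * rel[pct_dom].max())
    return curve, report
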
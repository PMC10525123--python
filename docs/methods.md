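# Methods

## Physical model

The calibration syringe is a horizontal piston–cylinder of nominal volume
V = 3.000 L, piston area S = 80 cm² and plunger travel L = 37.5 cm
(S·L = V holds by construction and is validated to 0.1%). A dead volume
(default 0.05 L — barrel dead space plus connecting tubing) stays
gas-filled at full insertion. The working gas is air treated as ideal and
adiabatic (γ = 1.4): piston friction, leakage and heat exchange are
neglected. All pressures are handled internally in Pa and referenced to
barometric pressure Pb (default 101 325 Pa); unit labels travel with every
series so mismatches fail loudly.

The pneumotachograph is a lumped monotone resistance
ΔP(Q) = k1·Q + k2·Q·|Q|, the one-dimensional collapse of a porous-media
resistance (a viscous plus an inertial term). Defaults k1 = 60 Pa·s/L,
k2 = 4 Pa·s²/L² place the spirometric range 1–14 L/s between ~64 Pa and
~1.6 kPa — sub-kPa drops at ordinary flows, consistent with 10 kPa-class
gauge sensors. The law is odd and strictly increasing, so its inverse is
the closed-form root of a signed quadratic.

## Stroke simulation

The plunger follows x(t) = A·(1 − cos 2πft): one full stroke of 2A per
half period, peak speed 2πAf. The barrel gas is tracked as
*ambient-equivalent content* C — the volume the gas would occupy at Pb
after adiabatic re-expansion — so that outflow bookkeeping is exact:

    P(t) = Pb · (C/V_in)^γ,    ΔP(Q) = P − Pb,    dC/dt = −Q.

A simulated recording consists of a rest pre-roll (default 0.3 s, later
used to zero-reference the gauge sensor), the sweep, and a settle phase
with the plunger at rest until |gauge| < 0.5 Pa (at most 5 s), so the
cumulative output of a full stroke converges to the nominal 3 L.

**Numerical choice.** The scalar content ODE is stiff near the stroke
ends: the pressure-relaxation time constant V/(γ·P_abs·dQ/dΔP) falls to
tens of microseconds when V_in approaches the dead volume. A fixed-step
explicit integrator at a practical step size diverges there, so the ODE
is integrated with the stiffness-switching LSODA method (rtol 1e-9,
dense output) over the three analytic phases — the pre-roll is exactly
static and skipped — and the channels are sampled onto a uniform output
grid (default 1e-4 s). Content conservation closes to ~1e-7 L over a
stroke and halving the grid step changes the cumulative output by < 1e-6
of 3 L.

**Sensor model.** Channels are resampled to their native rates
(pressures 250 Hz, displacement 60 Hz = the video frame rate), given
additive Gaussian noise (defaults: σ_gauge = 5 Pa, σ_ΔP = 2 Pa,
σ_displacement = 0.02 cm) and uniformly quantized (12-bit default) over
stated full-scale spans (±10 kPa for pressures, 0–40 cm for
displacement). All randomness flows from one integer seed.

**Peak-flow targeting.** Validation suites tile a requested peak-flow
range with alternating push/pull full strokes. The frequency for a target
peak is found by fixed-point refinement against coarse simulations,
starting from the incompressible guess 2πAf·S/1000 = target; it converges
in ≤ 3 iterations to 0.5%.

## Compression correction

With V_in the instantaneous in-cylinder volume, the correction

    Vc = V_in·[((Psyr + Pb)/Pb)^(1/γ) − 1]        (default form)

is algebraically identical to the ambient-equivalent-content bookkeeping
above, which is why the simulator round trip closes essentially exactly on
noise-free data. A variant referencing the pre-compression volume,
Vc = V_in·[1 − (Pb/(Psyr+Pb))^(1/γ)], is provided (`form="conservative"`);
the two agree to first order in Psyr/Pb — the gap is (Psyr/Pb)²/γ²·V_in,
< 0.2 mL at 2 kPa — far below sensor noise at spirometric pressures.
Corrected output volume is `swept − Vc` for push and `swept + Vc` for pull
(Vc < 0 there); the sign convention is fixed by volume conservation, which
the round-trip tests enforce. The first 0.2 s of each recording (plunger
at rest) defines the gauge baseline and the displacement origin,
absorbing sensor offset drift; displacement noise slightly outside
[0, travel] is clipped. The real output flow is the central-difference
derivative of the corrected volume (one-sided at the ends), so its
trapezoid integral reproduces the net volume change to O(dt²).

## Signal chain

Filtering uses a 5th-order Butterworth low-pass at 25 Hz (250 Hz
sampling). The default is zero-phase forward–backward application:
calibration is an offline computation, and causal phase lag would bias
the pairing of ΔP with flow. A causal single-pass mode is retained for
parity with live acquisition. Stream fusion linearly interpolates the
60 fps displacement onto the 250 Hz pressure grid over the common time
span; an optional cross-correlation search estimates and removes an
integer-sample lag between the displacement-derived kinematic flow and
ΔP (magnitude envelopes are correlated so the estimate works for both
stroke directions). Lags above 0.5 s are reported but not applied.

## Marker tracking

The renderer draws a saturated red rectangular marker (12×12 px) on a
neutral gray background (320×180, 60 fps, 7 px/cm by default) translating
per the piston kinematics, with coverage-weighted (anti-aliased) edges so
the photometric centroid moves with sub-pixel fidelity, plus i.i.d.
Gaussian pixel noise (σ = 2 of 255). The marker hue must differ from any
saturated background hue by ≥ 30°.

The tracker is classic mean shift without model update: a 16-bin hue
histogram gated at S ≥ 0.3, V ≥ 0.2 is learned from the initial window on
frame 0; per frame, the back-projected weight map's centroid relocates
the window until the shift is < 1 px or 10 iterations. Bin count, gates
and termination are declared defaults of this implementation. Losing all
window weight for three consecutive frames aborts tracking. Displacement
is the horizontal trajectory divided by the known pixel scale (motion is
assumed axial), and stroke volume is peak |displacement| × S. On rendered
fixtures the tracker agrees with a brute-force marker-pixel centroid to
≲ 0.2 px RMS and recovers stroke volumes within ~0.1% of 3 L.

## Calibration and validation

(ΔP, Q) pairs pooled across strokes are fitted with a least-squares
polynomial Q(ΔP), default order 3 (configurable 1–5; low orders follow
common spirometric practice). Because the resistance law is odd, the
default fit is *odd-symmetric*: the polynomial acts on |ΔP| against
sign(ΔP)·Q and the sign is restored on evaluation. A single raw
polynomial in signed ΔP is available (`symmetry="none"`) but markedly
less accurate — a cubic forced through the sign-change kink at ΔP = 0
leaves ~8% error at 14 L/s, versus ~1% for the folded fit. The intercept
is retained by default (a zero-through-origin option exists, since
ΔP = 0 ⇒ Q = 0 physically); optional inverse-density weighting
counteracts the oversampling of low pressures by slow strokes. R²,
residual RMS and the fitted ΔP range are stored with the curve;
evaluation outside the range is flagged as extrapolation, never clipped.

Validation extracts each waveform's peak flow as the maximum |flow| of
the calibrated, zero-phase-filtered ΔP trace, compares against the true
simulated peak under the ATS rule (tolerance = max(5% of reading,
0.200 L/s), inclusive; magnitudes, so pull waveforms are judged like
push), and summarises agreement with Bland–Altman bias ± 1.96·SD (SD with
n − 1).

## Study conditions and problem sizes

The reference studies in `pntcal.benchmarks` (also run by
`scripts/acceptance.py`) use: 20 calibration strokes and 20 held-out
validation strokes (10 push + 10 pull each) tiling 1–14 L/s with default
noise and 12-bit quantization; 20 rendered videos (320×180, 60 fps,
sweep frequencies 0.12–0.5 Hz, default pixel noise) of full 37.5 cm
strokes; and 14 constant flow levels (1..14 L/s, 10 replicates, 0.5%
multiplicative ΔP noise) for the fit-quality study. Held-out validation
waveforms are independent simulations with independent sensor-noise
realizations.

## What the synthetic data do and do not capture

The generator reproduces the measurement chain's structure — compressible
stroke dynamics through a monotone nonlinear resistance, sensor rates,
noise, quantization, video-based displacement — but not: tap-position
effects and backflow at the barrel tap (the lumped model has a single
pressure node, so the PNT ΔP equals the in-cylinder gauge up to noise),
Bluetooth/video clock skew (an optional lag search is provided instead),
illumination changes or lens distortion in the video, temperature drift,
or leakage. Passing tests therefore demonstrate the correctness and
numerical robustness of the algorithms under the stated physics, not the
accuracy of any particular hardware realization.

## Known limitations

* The displacement-noise default (0.02 cm) assumes marker tracking of the
  quality the renderer supports; blurrier real video would raise the
  differentiation noise in the flow reference.
* Per-direction calibration curves are supported but the default pools
  directions under odd symmetry; a strongly direction-asymmetric PNT
  would need the per-direction mode.
* The gauge pressure is assumed measurable at the barrel; a user-supplied
  linear map can stand in for an upstream-tap surrogate, but no such map
  is derived here.
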
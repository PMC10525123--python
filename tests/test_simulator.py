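"""Stroke simulator: kinematics, resistance law, conservation, limits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pntcal import (GasParameters, PistonMotion, ResistanceModel,
                    SyringeGeometry, generate_validation_suite,
                    invert_pressure_drop, piston_displacement,
                    piston_velocity, pressure_drop, sample_sensors,
                    simulate_stroke)
from pntcal.exceptions import DegenerateModelError

GEO = SyringeGeometry()
GAS = GasParameters()
RES = ResistanceModel()


class TestKinematics:
    def test_velocity_values(self):
        m = PistonMotion(amplitude=18.75, frequency=0.25)
        assert piston_velocity(0.0, m) == 0.0
        peak = 2 * math.pi * 18.75 * 0.25
        assert piston_velocity(1 / (4 * 0.25), m) == pytest.approx(peak)
        assert piston_velocity(1.0, m) == pytest.approx(29.452, abs=1e-3)

    def test_displacement_full_stroke(self):
        m = PistonMotion(amplitude=18.75, frequency=0.25)
        assert piston_displacement(0.0, m) == 0.0
        assert piston_displacement(1 / (2 * 0.25), m) == pytest.approx(37.5)
        assert piston_displacement(1 / (2 * 0.25), m) == \
            pytest.approx(GEO.plunger_travel)

    def test_displacement_derivative_matches_velocity(self):
        m = PistonMotion(amplitude=10.0, frequency=0.4)
        dt = 1e-5
        t = np.linspace(dt, m.duration - dt, 200)
        numeric = (piston_displacement(t + dt, m)
                   - piston_displacement(t - dt, m)) / (2 * dt)
        np.testing.assert_allclose(numeric, piston_velocity(t, m),
                                   atol=1e-5 * m.peak_speed)


class TestResistanceLaw:
    def test_values_and_oddness(self):
        r = ResistanceModel(k1=60, k2=4)
        assert pressure_drop(0.0, r) == 0.0
        assert pressure_drop(5.0, r) == pytest.approx(400.0)
        q = np.linspace(-14, 14, 57)
        np.testing.assert_allclose(pressure_drop(-q, r),
                                   -pressure_drop(q, r), atol=1e-12)

    def test_inverse_round_trip(self):
        q = np.linspace(-14, 14, 29)
        dp = pressure_drop(q, RES)
        np.testing.assert_allclose(invert_pressure_drop(dp, RES), q,
                                   rtol=1e-9, atol=1e-12)

    def test_linear_limit(self):
        r = ResistanceModel(k1=80, k2=0)
        assert invert_pressure_drop(400.0, r) == pytest.approx(5.0)

    def test_degenerate_model_rejected(self):
        with pytest.raises((DegenerateModelError, ValueError)):
            r = ResistanceModel(k1=60, k2=4)
            r.k1 = r.k2 = 0.0       # bypass constructor validation
            invert_pressure_drop(10.0, r)

    @given(st.floats(-20, 20))
    def test_round_trip_property(self, q):
        dp = pressure_drop(q, RES)
        assert invert_pressure_drop(dp, RES) == pytest.approx(q, abs=1e-9)


class TestSimulateStroke:
    def test_low_resistance_limit_approaches_kinematic_flow(self):
        # as resistance vanishes, gauge pressure → 0 and flow → S·v/1000
        m = PistonMotion(amplitude=18.75, frequency=0.5)
        r_small = ResistanceModel(k1=1.0, k2=0.0)
        rec = simulate_stroke(GEO, GAS, r_small, m, settle=0.0)
        kin = GEO.piston_area * piston_velocity(
            np.maximum(rec.t - 0.3, 0.0), m) / 1000.0
        kin[rec.t < 0.3] = 0.0
        assert np.max(np.abs(rec.gauge)) < 10.0
        assert np.max(np.abs(rec.flow - kin)) < 1e-2
        # an order of magnitude more resistance departs much further
        rec_big = simulate_stroke(GEO, GAS, RES, m, settle=0.0)
        assert np.max(np.abs(rec_big.flow - kin)) > \
            10 * np.max(np.abs(rec.flow - kin))

    def test_slow_vs_fast_stroke_compression(self):
        slow = simulate_stroke(GEO, GAS, RES,
                               PistonMotion(18.75, 0.05))
        fast = simulate_stroke(GEO, GAS, RES,
                               PistonMotion(18.75, 0.5))
        assert np.max(np.abs(slow.gauge)) < np.max(np.abs(fast.gauge))
        # slow stroke: output ≈ swept volume throughout the sweep
        assert slow.stroke_volume == pytest.approx(3.0, rel=5e-4)

    def test_conservation(self, push_stroke):
        rec = push_stroke
        content_change = rec.meta["content_start"] - rec.meta["content_end"]
        assert abs(content_change - rec.cumulative[-1]) <= 0.001 * 3.0

    def test_flow_sign_matches_direction(self, push_stroke, pull_stroke):
        sweep = (push_stroke.t > 0.35) & (push_stroke.t < 0.3
                                          + push_stroke.motion.duration)
        assert np.all(push_stroke.flow[sweep] > 0)
        sweep = (pull_stroke.t > 0.35) & (pull_stroke.t < 0.3
                                          + pull_stroke.motion.duration)
        assert np.all(pull_stroke.flow[sweep] < 0)
        # pressure drop and flow share sign everywhere
        for rec in (push_stroke, pull_stroke):
            assert np.all(rec.pnt_dp * rec.flow >= 0)

    def test_grid_refinement(self):
        m = PistonMotion(amplitude=18.75, frequency=0.5)
        v1 = simulate_stroke(GEO, GAS, RES, m, dt=2e-4).stroke_volume
        v2 = simulate_stroke(GEO, GAS, RES, m, dt=1e-4).stroke_volume
        assert abs(v1 - v2) / 3.0 < 2e-4


class TestSampleSensors:
    def test_noise_free_unquantized_matches_truth(self, push_stroke):
        tr = sample_sensors(push_stroke,
                            noise_sigma={"gauge": 0, "pnt_dp": 0,
                                         "displacement": 0},
                            bits=None, seed=1)
        grid = tr.gauge.t
        np.testing.assert_allclose(
            tr.gauge.values,
            np.interp(grid, push_stroke.t, push_stroke.gauge), atol=1e-12)
        assert tr.gauge.fs == pytest.approx(250.0)
        assert tr.displacement.fs == pytest.approx(60.0)

    def test_same_seed_reproducible(self, push_stroke):
        a = sample_sensors(push_stroke, seed=7)
        b = sample_sensors(push_stroke, seed=7)
        np.testing.assert_array_equal(a.pnt_dp.values, b.pnt_dp.values)
        c = sample_sensors(push_stroke, seed=8)
        assert not np.array_equal(a.pnt_dp.values, c.pnt_dp.values)

    def test_noise_level_calibrated(self, geometry, gas_params, resistance):
        # slow stroke → ≥ 2500 pressure samples for the σ estimate
        rec = simulate_stroke(geometry, gas_params, resistance,
                              PistonMotion(18.75, 0.045))
        clean = sample_sensors(rec, noise_sigma={"gauge": 0, "pnt_dp": 0,
                                                 "displacement": 0},
                               bits=None, seed=0)
        noisy = sample_sensors(rec, noise_sigma={"gauge": 0, "pnt_dp": 2.0,
                                                 "displacement": 0},
                               bits=None, seed=0)
        resid = noisy.pnt_dp.values - clean.pnt_dp.values
        assert resid.size >= 2500
        assert np.std(resid) == pytest.approx(2.0, rel=0.10)

    def test_few_bits_warn(self, push_stroke):
        with pytest.warns(UserWarning):
            sample_sensors(push_stroke, bits=6, seed=0)


class TestValidationSuite:
    def test_tiles_range_with_alternating_directions(self, geometry,
                                                     gas_params, resistance):
        suite = generate_validation_suite(6, (2.0, 10.0), geometry,
                                          gas_params, resistance, seed=0,
                                          dt=5e-4)
        dirs = [r.direction for r in suite]
        assert dirs == ["push", "pull"] * 3
        targets = [r.meta["target_peak_flow"] for r in suite]
        np.testing.assert_allclose(targets, [2, 2, 6, 6, 10, 10])
        for rec in suite:
            assert rec.peak_flow == pytest.approx(
                rec.meta["target_peak_flow"], rel=0.02)

    def test_single_stroke(self, geometry, gas_params, resistance):
        suite = generate_validation_suite(1, (1.0, 14.0), geometry,
                                          gas_params, resistance, dt=5e-4)
        assert len(suite) == 1 and suite[0].direction == "push"

    def test_deterministic(self, geometry, gas_params, resistance):
        a = generate_validation_suite(2, (3.0, 5.0), geometry, gas_params,
                                      resistance, seed=5, dt=5e-4)
        b = generate_validation_suite(2, (3.0, 5.0), geometry, gas_params,
                                      resistance, seed=5, dt=5e-4)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.flow, rb.flow)
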
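import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pntcal import (Config, GasParameters, PistonMotion, ResistanceModel,
                    SyringeGeometry, simulate_stroke)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return SyringeGeometry()


@pytest.fixture(scope="session")
def gas_params():
    return GasParameters()


@pytest.fixture(scope="session")
def resistance():
    return ResistanceModel()


@pytest.fixture(scope="session")
def config():
    return Config(seed=0)


@pytest.fixture(scope="session")
def push_stroke(geometry, gas_params, resistance):
    """A clean medium-speed full push stroke (peak ≈ 6.6 L/s)."""
    motion = PistonMotion(amplitude=18.75, frequency=0.7)
    return simulate_stroke(geometry, gas_params, resistance, motion,
                           direction="push")


@pytest.fixture(scope="session")
def pull_stroke(geometry, gas_params, resistance):
    motion = PistonMotion(amplitude=18.75, frequency=0.7)
    return simulate_stroke(geometry, gas_params, resistance, motion,
                           direction="pull")


@pytest.fixture(scope="session")
def rendered_sequence():
    """One rendered full-stroke marker video with default noise."""
    from pntcal import render_frames
    motion = PistonMotion(amplitude=18.75, frequency=0.3)
    return render_frames(motion, seed=3)


def brute_force_marker_centroid(frame, marker_color, tol=60.0):
    """Oracle: centroid of pixels within *tol* (RGB distance) of the marker."""
    diff = frame.astype(float) - np.asarray(marker_color, dtype=float)
    mask = np.sqrt((diff ** 2).sum(axis=-1)) < tol
    rows, cols = np.nonzero(mask)
    return rows.mean(), cols.mean()
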
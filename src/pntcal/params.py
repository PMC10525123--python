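"""Physical parameters of the syringe, the gas, the flow-resistance element
and the drive motion, plus the run configuration.

Defaults describe a commercial 3 L calibration syringe (plunger travel
37.5 cm, hence piston area 80 cm²), dry air (γ = 1.4) at standard
barometric pressure, and a Fleisch-type pneumotachograph whose pressure
drop over the spirometric 1–14 L/s range spans roughly 60 Pa to 1.6 kPa.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .exceptions import DomainError


@dataclass
class SyringeGeometry:
    """Piston-cylinder geometry of the calibration syringe.

    ``piston_area`` (cm²) × ``plunger_travel`` (cm) must equal the nominal
    swept volume (L, ×1000 cm³) to within 0.1%.  ``dead_volume`` (L) is the
    barrel dead space plus connecting tubing that stays gas-filled at full
    insertion.
    """

    piston_area: float = 80.0        # cm²
    plunger_travel: float = 37.5     # cm
    nominal_volume: float = 3.0      # L
    dead_volume: float = 0.05        # L

    def __post_init__(self) -> None:
        for name in ("piston_area", "plunger_travel", "nominal_volume",
                     "dead_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        swept = self.piston_area * self.plunger_travel        # cm³
        if abs(swept - 1000.0 * self.nominal_volume) > 1e-3 * swept:
            raise ValueError(
                "piston_area × plunger_travel must equal nominal_volume "
                f"within 0.1% (got {swept / 1000.0:.4f} L vs "
                f"{self.nominal_volume} L)")


@dataclass
class GasParameters:
    """Thermodynamic constants of the working gas (air by default)."""

    gamma: float = 1.4                 # heat-capacity ratio cp/cv
    barometric_pressure: float = 101325.0  # Pa

    def __post_init__(self) -> None:
        if not self.gamma > 1:
            raise ValueError("gamma must exceed 1")
        if not self.barometric_pressure > 0:
            raise ValueError("barometric_pressure must be positive")


@dataclass
class ResistanceModel:
    """Lumped pressure-drop law of the pneumotachograph.

    ΔP(Q) = k1·Q + k2·Q·|Q| — a linear (viscous) term plus a quadratic
    (inertial) term, the lumped equivalent of a porous-media resistance.
    Strictly monotone whenever k1 + k2 > 0, so it has a unique inverse.
    """

    k1: float = 60.0   # Pa·s/L
    k2: float = 4.0    # Pa·s²/L²

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("resistance coefficients must be non-negative")
        if self.k1 == 0 and self.k2 == 0:
            raise ValueError("k1 and k2 cannot both be zero")


@dataclass
class PistonMotion:
    """Sinusoidal plunger drive x(t) = A·(1 − cos 2πft).

    One full stroke of 2A is swept per half period; the default duration is
    therefore 1/(2f).  Peak speed is 2πAf (cm/s).
    """

    amplitude: float            # cm (A); stroke length is 2A
    frequency: float            # Hz
    duration: float | None = None  # s; defaults to half a period

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.frequency <= 0:
            raise ValueError("amplitude and frequency must be positive")
        if self.duration is None:
            self.duration = 0.5 / self.frequency
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def peak_speed(self) -> float:
        """Maximum plunger speed 2πAf in cm/s."""
        import math
        return 2.0 * math.pi * self.amplitude * self.frequency

    def check_fits(self, geometry: SyringeGeometry) -> None:
        if 2.0 * self.amplitude > geometry.plunger_travel * (1 + 1e-9):
            raise DomainError(
                f"stroke 2A = {2 * self.amplitude} cm exceeds plunger travel "
                f"{geometry.plunger_travel} cm")


#: per-channel 1-σ sensor noise used by default when sampling a stroke
DEFAULT_NOISE_SIGMA = {"gauge": 5.0, "pnt_dp": 2.0, "displacement": 0.02}

#: full-scale spans used for uniform ADC quantization
DEFAULT_FULL_SCALE = {"gauge": (-10000.0, 10000.0),
                      "pnt_dp": (-10000.0, 10000.0),
                      "displacement": (0.0, 40.0)}


@dataclass
class Config:
    """Run configuration shared by the CLI, the pipeline and the examples."""

    geometry: SyringeGeometry = field(default_factory=SyringeGeometry)
    gas: GasParameters = field(default_factory=GasParameters)
    resistance: ResistanceModel = field(default_factory=ResistanceModel)
    pressure_fs: float = 250.0    # Hz
    video_fps: float = 60.0       # Hz
    filter_order: int = 5
    filter_cutoff: float = 25.0   # Hz
    poly_order: int = 3
    seed: int = 0
    noise_sigma: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SIGMA))
    adc_bits: int = 12
    sim_dt: float = 1e-4          # s, integrator step

    def __post_init__(self) -> None:
        if not self.filter_cutoff < self.pressure_fs / 2:
            raise ValueError("filter_cutoff must be below the pressure "
                             "Nyquist frequency")
        if not 1 <= self.poly_order <= 5:
            raise ValueError("poly_order must be in [1, 5]")
        if self.filter_order < 1:
            raise ValueError("filter_order must be ≥ 1")
        if self.sim_dt <= 0 or self.sim_dt > 1e-3:
            raise ValueError("sim_dt must lie in (0, 1e-3] s")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        d = dict(d)
        for key, typ in (("geometry", SyringeGeometry),
                         ("gas", GasParameters),
                         ("resistance", ResistanceModel)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
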
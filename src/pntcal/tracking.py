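"""Synthetic marker videos and HSV histogram mean-shift tracking.

The plunger handle carries a high-saturation colored marker filmed against
a neutral background; its horizontal image trajectory is a surrogate for
plunger displacement.  ``render_frames`` produces such footage
synthetically — a colored rectangle translating per the piston kinematics,
drawn with sub-pixel (coverage-weighted) edges over a noisy gray
background.  The tracker is classic mean shift: a hue histogram is learned
once from the initial window, every frame is back-projected to a weight
map, and the window relocates to the weighted centroid until convergence.
Saturation/value gating keeps near-gray background pixels out of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv

from .exceptions import RenderError, TrackingError
from .params import PistonMotion
from .simulate import piston_displacement
from .timeseries import TimeSeries


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """Ordered 8-bit RGB frames with a frame rate and a pixel scale."""

    frames: np.ndarray          # (N, H, W, 3) uint8
    fps: float
    px_per_cm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[-1] != 3 or f.dtype != np.uint8:
            raise ValueError("frames must be (N, H, W, 3) uint8")
        if self.fps <= 0 or self.px_per_cm <= 0:
            raise ValueError("fps and px_per_cm must be positive")
        self.frames = f

    @property
    def n(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def save(self, directory) -> None:
        """Write a PNG sequence plus a JSON manifest (fps, px_per_cm)."""
        import json

        import imageio.v3 as iio
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, fr in enumerate(self.frames):
            iio.imwrite(d / f"frame_{i:05d}.png", fr)
        manifest = {"fps": self.fps, "px_per_cm": self.px_per_cm,
                    "n_frames": int(self.n), "meta": self.meta}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))

    @classmethod
    def load(cls, directory) -> "FrameSequence":
        import json

        import imageio.v3 as iio
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        frames = np.stack([iio.imread(p)
                           for p in sorted(d.glob("frame_*.png"))])
        return cls(frames=frames.astype(np.uint8), fps=manifest["fps"],
                   px_per_cm=manifest["px_per_cm"],
                   meta=manifest.get("meta", {}))


@dataclass
class TrackWindow:
    """Search window: float center (row, col) and integer half extents."""

    center: tuple[float, float]
    half_extent: tuple[int, int] = (14, 14)

    def bounds(self, shape: tuple[int, int]) -> tuple[int, int, int, int]:
        """Integer (r0, r1, c0, c1) slice bounds clipped to the frame."""
        r, c = self.center
        hr, hc = self.half_extent
        r0 = max(0, int(round(r)) - hr)
        r1 = min(shape[0], int(round(r)) + hr + 1)
        c0 = max(0, int(round(c)) - hc)
        c1 = min(shape[1], int(round(c)) + hc + 1)
        if r0 >= r1 or c0 >= c1:
            raise ValueError("window lies outside the frame")
        return r0, r1, c0, c1


@dataclass
class Trajectory:
    """Per-frame window centers (row, col) in pixels."""

    centers: np.ndarray         # (N, 2) float
    fps: float
    lost: np.ndarray | None = None   # bool per frame

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 2 or self.centers.shape[1] != 2:
            raise ValueError("centers must be (N, 2)")
        if not np.isfinite(self.centers).all():
            raise ValueError("centers must be finite")

    @property
    def cols(self) -> np.ndarray:
        return self.centers[:, 1]


@dataclass
class MarkerSpec:
    """Rendered marker: RGB color and rectangle size in pixels."""

    color: tuple[int, int, int] = (210, 30, 30)   # saturated red
    size_px: tuple[int, int] = (12, 12)           # (height, width)


@dataclass
class BackgroundSpec:
    """Neutral background: RGB color and additive pixel noise sigma."""

    color: tuple[int, int, int] = (128, 128, 128)
    noise_sigma: float = 2.0


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _hue_deg(rgb: tuple[int, int, int]) -> float:
    arr = np.asarray(rgb, dtype=np.uint8).reshape(1, 1, 3)
    return float(rgb2hsv(arr)[0, 0, 0] * 360.0)


def _saturation(rgb: tuple[int, int, int]) -> float:
    arr = np.asarray(rgb, dtype=np.uint8).reshape(1, 1, 3)
    return float(rgb2hsv(arr)[0, 0, 1])


def _coverage_1d(n: int, lo: float, hi: float) -> np.ndarray:
    """Fraction of each unit pixel cell [i−½, i+½) covered by [lo, hi).

    Pixel *i* is centered on the integer coordinate *i*, matching the
    index-coordinate centroids used by the tracker.
    """
    i = np.arange(n, dtype=float)
    return np.clip(np.minimum(i + 0.5, hi) - np.maximum(i - 0.5, lo),
                   0.0, 1.0)


def render_frames(motion: PistonMotion,
                  marker: MarkerSpec | None = None,
                  background: BackgroundSpec | None = None,
                  shape: tuple[int, int] = (180, 320),
                  fps: float = 60.0,
                  px_per_cm: float = 7.0,
                  seed: int = 0,
                  direction_sign: int = 1,
                  start_col: float | None = None,
                  pre_hold: float = 0.2,
                  post_hold: float = 0.2) -> FrameSequence:
    """Render a marker translating horizontally per the piston kinematics.

    The marker rectangle is drawn with coverage-weighted (anti-aliased)
    edges so its photometric centroid moves with sub-pixel fidelity; i.i.d.
    Gaussian pixel noise is added and clipped to 8 bits.  The sequence
    holds still for *pre_hold* seconds before the sweep and *post_hold*
    after, mimicking a recorded stroke.  ``direction_sign`` (+1/−1) sets
    the direction of image motion; the analytic marker center per frame is
    stored in ``meta["true_cols"]``.
    """
    marker = marker or MarkerSpec()
    background = background or BackgroundSpec()
    h, w = shape
    mh, mw = marker.size_px
    if _saturation(background.color) > 0.25:
        d = abs(_hue_deg(marker.color) - _hue_deg(background.color))
        if min(d, 360.0 - d) < 30.0:
            raise ValueError("marker hue must differ from a saturated "
                             "background hue by at least 30°")
    travel_px = 2.0 * motion.amplitude * px_per_cm
    if start_col is None:
        margin = mw / 2.0 + 4.0
        start_col = margin if direction_sign > 0 else w - margin
    row_c = h / 2.0
    n_frames = int(round((pre_hold + motion.duration + post_hold) * fps)) + 1
    t = np.arange(n_frames) / fps - pre_hold
    cols = start_col + direction_sign * piston_displacement(t, motion) \
        * px_per_cm
    if np.any(cols - mw / 2 < 0) or np.any(cols + mw / 2 > w) \
            or row_c - mh / 2 < 0 or row_c + mh / 2 > h:
        raise RenderError(
            f"marker (travel {travel_px:.0f} px) leaves the {w}px frame; "
            "reduce px_per_cm or enlarge the frame")

    rng = np.random.default_rng(seed)
    bg = np.asarray(background.color, dtype=float)
    fg = np.asarray(marker.color, dtype=float)
    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    cov_r = _coverage_1d(h, row_c - mh / 2.0, row_c + mh / 2.0)
    for k in range(n_frames):
        cov_c = _coverage_1d(w, cols[k] - mw / 2.0, cols[k] + mw / 2.0)
        alpha = cov_r[:, None] * cov_c[None, :]
        img = bg[None, None, :] * (1.0 - alpha[..., None]) \
            + fg[None, None, :] * alpha[..., None]
        if background.noise_sigma > 0:
            img = img + rng.normal(0.0, background.noise_sigma, img.shape)
        frames[k] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return FrameSequence(frames=frames, fps=fps, px_per_cm=px_per_cm,
                         meta={"true_cols": cols.tolist(),
                               "true_row": row_c, "seed": seed,
                               "direction_sign": direction_sign})


# ---------------------------------------------------------------------------
# mean-shift tracking
# ---------------------------------------------------------------------------

def to_hsv(frame: np.ndarray) -> np.ndarray:
    """8-bit RGB frame → HSV with H in [0, 360), S and V in [0, 1]."""
    if frame.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB frame")
    hsv = rgb2hsv(frame)
    hsv[..., 0] *= 360.0
    return hsv


def hue_histogram(frame_hsv: np.ndarray, window: TrackWindow,
                  bins: int = 16,
                  min_sv: tuple[float, float] = (0.3, 0.2)) -> np.ndarray:
    """Normalized hue histogram of the window's sufficiently colorful pixels.

    Pixels below the saturation/value thresholds are ignored; if none
    qualify an all-zero histogram is returned (degenerate-model signal).
    """
    r0, r1, c0, c1 = window.bounds(frame_hsv.shape[:2])
    patch = frame_hsv[r0:r1, c0:c1]
    mask = (patch[..., 1] >= min_sv[0]) & (patch[..., 2] >= min_sv[1])
    if not mask.any():
        return np.zeros(bins)
    hist, _ = np.histogram(patch[..., 0][mask], bins=bins,
                           range=(0.0, 360.0))
    return hist / hist.sum()


def back_projection(frame_hsv: np.ndarray, hist: np.ndarray,
                    min_sv: tuple[float, float] = (0.3, 0.2)) -> np.ndarray:
    """Per-pixel weight in [0, 1]: the model mass of the pixel's hue bin."""
    bins = hist.shape[0]
    idx = np.minimum((frame_hsv[..., 0] / 360.0 * bins).astype(int),
                     bins - 1)
    weights = hist[idx]
    qualify = (frame_hsv[..., 1] >= min_sv[0]) & \
        (frame_hsv[..., 2] >= min_sv[1])
    return np.where(qualify, weights, 0.0)


def meanshift_step(weights: np.ndarray,
                   window: TrackWindow) -> tuple[TrackWindow, bool]:
    """One relocation to the weighted centroid inside the window.

    Returns the updated window and a lost-track flag (True when the window
    contains no weight; the center is then kept).
    """
    r0, r1, c0, c1 = window.bounds(weights.shape)
    w = weights[r0:r1, c0:c1]
    total = w.sum()
    if total <= 0:
        return TrackWindow(center=window.center,
                           half_extent=window.half_extent), True
    rows = np.arange(r0, r1, dtype=float)
    cols = np.arange(c0, c1, dtype=float)
    r = float((w.sum(axis=1) * rows).sum() / total)
    c = float((w.sum(axis=0) * cols).sum() / total)
    return TrackWindow(center=(r, c), half_extent=window.half_extent), False


def track(frames: FrameSequence, init: TrackWindow,
          bins: int = 16, min_sv: tuple[float, float] = (0.3, 0.2),
          eps: float = 1.0, max_iter: int = 10) -> Trajectory:
    """Track the marker through the sequence with classic mean shift.

    The hue model is built once from *init* on frame 0 and never updated.
    Per frame the window iterates to convergence (center shift < *eps* px
    or *max_iter* iterations).  Three consecutive lost frames raise
    :class:`TrackingError`.
    """
    hsv0 = to_hsv(frames.frames[0])
    hist = hue_histogram(hsv0, init, bins=bins, min_sv=min_sv)
    if hist.sum() == 0:
        raise TrackingError("no colorful pixels in the initial window")
    window = init
    centers = np.empty((frames.n, 2))
    lost_flags = np.zeros(frames.n, dtype=bool)
    consecutive_lost = 0
    pad = max(window.half_extent) + 2
    for k in range(frames.n):
        frame = frames.frames[k]
        lost_this = False
        for _ in range(max_iter):
            r, c = window.center
            hr, hc = window.half_extent
            r0 = max(0, int(r) - hr - pad)
            r1 = min(frame.shape[0], int(r) + hr + pad + 1)
            c0 = max(0, int(c) - hc - pad)
            c1 = min(frame.shape[1], int(c) + hc + pad + 1)
            sub_hsv = to_hsv(frame[r0:r1, c0:c1])
            weights = back_projection(sub_hsv, hist, min_sv=min_sv)
            local = TrackWindow(center=(r - r0, c - c0),
                                half_extent=window.half_extent)
            new_local, lost_this = meanshift_step(weights, local)
            new = TrackWindow(center=(new_local.center[0] + r0,
                                      new_local.center[1] + c0),
                              half_extent=window.half_extent)
            shift = np.hypot(new.center[0] - window.center[0],
                             new.center[1] - window.center[1])
            window = new
            if lost_this or shift < eps:
                break
        centers[k] = window.center
        lost_flags[k] = lost_this
        consecutive_lost = consecutive_lost + 1 if lost_this else 0
        if consecutive_lost >= 3:
            raise TrackingError(f"lost track for 3 frames ending at {k}")
    return Trajectory(centers=centers, fps=frames.fps, lost=lost_flags)


def trajectory_to_displacement(traj: Trajectory,
                               px_per_cm: float) -> TimeSeries:
    """Horizontal displacement (cm) from frame 0; vertical motion discarded.

    The plunger is assumed to move along the syringe axis only, so the
    column coordinate alone carries displacement.  The sign follows image
    motion; take magnitudes for stroke volume.
    """
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    disp = (traj.cols - traj.cols[0]) / px_per_cm
    return TimeSeries(t0=0.0, dt=1.0 / traj.fps, values=disp, unit="cm")
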
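"""Synthetic fluoroscopy scenes with known hemidiaphragm kinematics.

No imaging data ships with this package, so every downstream stage
(tracking, smoothing, waveform analysis, classification) is exercised
against rendered frame sequences whose ground truth is known exactly.

A scene contains two dome-shaped intensity boundaries — dark lung above,
brighter abdomen below — one per hemidiaphragm.  Each dome apex oscillates
vertically as a sinusoid::

    row(t) = baseline_row - A * sin(2*pi*t/T + phase) + jitter

so a positive sine excursion moves the apex cranially (toward row 0),
mimicking the dome rising in expiration.  Quiet breathing uses periods
near 1.9 s; sniffing near 0.3 s.  Amplitudes of a few to a few tens of
pixels cover the clinically observed range at typical fluoroscopic
geometry.

The renderer is deliberately minimal: a downward-opening parabolic
contour per side, a one-pixel linear intensity ramp across the boundary
(sub-pixel apex information for the edge detector), additive Gaussian
pixel noise, and Gaussian jitter on the apex row.  It does not attempt
ribs, cardiac shadow or scatter.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GeometryError, InvalidParameterError
from .tracking import FrameSequence, TrajectorySeries

__all__ = [
    "MotionParams",
    "SceneConfig",
    "GroundTruth",
    "generate_trajectory",
    "render_frames",
    "make_scenario",
    "save_scenario",
    "SCENARIO_NAMES",
    "SCENARIO_MODES",
]

#: Background (lung) intensity of rendered frames, on a [0, 1] scale.
LUNG_LEVEL = 0.15

SCENARIO_NAMES = ("normal", "weakness", "paralysis")
SCENARIO_MODES = ("quiet", "sniff")


@dataclass(frozen=True)
class MotionParams:
    """Sinusoidal motion of one dome apex.

    Parameters
    ----------
    amplitude_px
        Peak excursion of the apex about its baseline, in pixels.
    period_s
        Respiratory period in seconds (~1.9 s quiet, ~0.3 s sniff).
    phase_deg
        Phase of the sinusoid at t=0, degrees; normalised to [0, 360).
    baseline_row
        Mean apex row (pixels from the image top; smaller = more cranial).
    noise_sd_px
        SD of additive Gaussian noise on generated trajectory samples.
    """

    amplitude_px: float
    period_s: float
    phase_deg: float
    baseline_row: float
    noise_sd_px: float = 0.0

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise InvalidParameterError(f"period_s must be > 0, got {self.period_s}")
        if self.amplitude_px < 0:
            raise InvalidParameterError("amplitude_px must be >= 0")
        if self.noise_sd_px < 0:
            raise InvalidParameterError("noise_sd_px must be >= 0")
        if self.baseline_row <= 0:
            raise InvalidParameterError("baseline_row must be > 0")
        object.__setattr__(self, "phase_deg", float(self.phase_deg) % 360.0)

    @property
    def phase_rad(self) -> float:
        return math.radians(self.phase_deg)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic fluoroscopy acquisition."""

    left_params: MotionParams
    right_params: MotionParams
    image_height: int = 256
    image_width: int = 256
    frame_rate_hz: float = 30.0
    duration_s: float = 8.0
    contrast: float = 0.6
    seed: int = 0
    # Dome geometry: parabolic contour row(c) = apex_row + curvature*(c-apex_col)^2
    dome_half_width_px: int = 40
    dome_curvature: float = 0.02
    # Noise model: Gaussian jitter on the rendered apex row + Gaussian pixel noise
    apex_jitter_sd_px: float = 0.3
    pixel_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise InvalidParameterError("frame_rate_hz must be > 0")
        if not 0 < self.contrast <= 1:
            raise InvalidParameterError("contrast must lie in (0, 1]")
        if self.n_frames < 2:
            raise InvalidParameterError(
                "duration_s * frame_rate_hz must yield at least 2 frames"
            )

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_s * self.frame_rate_hz))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        d["left_params"] = MotionParams(**d["left_params"])
        d["right_params"] = MotionParams(**d["right_params"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Reference kinematics recorded alongside a rendered sequence.

    ``left_elevation``/``right_elevation`` use the tracker's sign
    convention: elevation = reference_row - apex_row, so ascent (motion
    toward the image top) is positive.  The raw apex rows (including the
    rendered jitter) are kept as well so edge-level oracles can compare
    in image coordinates.
    """

    times: np.ndarray
    left_elevation: np.ndarray
    right_elevation: np.ndarray
    true_phase_offset_deg: float
    true_amplitude_scale: float
    left_apex_row: np.ndarray = field(default=None, repr=False)
    right_apex_row: np.ndarray = field(default=None, repr=False)
    reference_row: int = 0

    def __post_init__(self) -> None:
        n = len(self.times)
        for v in (self.left_elevation, self.right_elevation):
            if len(v) != n:
                raise InvalidParameterError("GroundTruth vectors must share length")
            if not np.all(np.isfinite(v)):
                raise InvalidParameterError("GroundTruth elevations must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "left_elev_px": self.left_elevation,
                "right_elev_px": self.right_elevation,
            }
        )


def _apex_rows(params: MotionParams, times: np.ndarray) -> np.ndarray:
    """Noiseless apex row trajectory for one side."""
    return params.baseline_row - params.amplitude_px * np.sin(
        2.0 * np.pi * times / params.period_s + params.phase_rad
    )


def generate_trajectory(
    params: MotionParams,
    times: np.ndarray,
    seed: int = 0,
    side: str = "left",
) -> TrajectorySeries:
    """Sample a noisy sinusoidal apex trajectory at the given times.

    elevation(t) = baseline_row - A*sin(2*pi*t/T + phase) + eps with
    eps ~ N(0, noise_sd_px^2) i.i.d.; deterministic for a given seed.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise InvalidParameterError("times must be a non-empty 1-D vector")
    if np.any(np.diff(times) <= 0):
        raise InvalidParameterError("times must be strictly increasing")
    values = _apex_rows(params, times)
    if params.noise_sd_px > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, params.noise_sd_px, size=len(times))
    return TrajectorySeries(
        times=times, elevation=values, side=side, source="synthetic"
    )


def _check_geometry(config: SceneConfig, rows: np.ndarray, label: str) -> None:
    depth = config.dome_curvature * config.dome_half_width_px**2
    if rows.min() < 1.0:
        raise GeometryError(
            f"{label} dome apex reaches row {rows.min():.1f}; must stay >= 1"
        )
    if rows.max() + depth > config.image_height - 2:
        raise GeometryError(
            f"{label} dome contour reaches row {rows.max() + depth:.1f}; "
            f"must stay <= {config.image_height - 2}"
        )


def render_frames(config: SceneConfig) -> tuple[FrameSequence, GroundTruth]:
    """Render a frame sequence and its exact ground truth.

    Each frame holds two parabolic bright/dark boundaries whose apices
    follow the configured sinusoids (plus seeded apex jitter); Gaussian
    pixel noise is added last.  Deterministic for a given config.
    """
    h, w = config.image_height, config.image_width
    times = config.times()
    ss = np.random.SeedSequence(config.seed)
    jit_l, jit_r, pix = (np.random.default_rng(s) for s in ss.spawn(3))

    rows_l = _apex_rows(config.left_params, times)
    rows_r = _apex_rows(config.right_params, times)
    if config.apex_jitter_sd_px > 0:
        rows_l = rows_l + jit_l.normal(0.0, config.apex_jitter_sd_px, len(times))
        rows_r = rows_r + jit_r.normal(0.0, config.apex_jitter_sd_px, len(times))
    _check_geometry(config, rows_l, "left")
    _check_geometry(config, rows_r, "right")

    apex_col_l, apex_col_r = w // 4, (3 * w) // 4
    half = config.dome_half_width_px
    cols_l = np.arange(apex_col_l - half, apex_col_l + half + 1)
    cols_r = np.arange(apex_col_r - half, apex_col_r + half + 1)
    if cols_l.min() < 0 or cols_r.max() >= w or cols_l.max() >= cols_r.min():
        raise GeometryError("dome spans fall outside the image or overlap")

    bright = LUNG_LEVEL + config.contrast * (1.0 - LUNG_LEVEL)
    row_idx = np.arange(h, dtype=np.float64)[:, None]
    par_l = config.dome_curvature * (cols_l - apex_col_l) ** 2
    par_r = config.dome_curvature * (cols_r - apex_col_r) ** 2

    frames = np.full((len(times), h, w), LUNG_LEVEL, dtype=np.float32)
    for i in range(len(times)):
        for cols, par, apex in ((cols_l, par_l, rows_l[i]), (cols_r, par_r, rows_r[i])):
            contour = apex + par  # boundary row per column
            # 1-px linear ramp across the boundary -> sub-pixel apex position
            coverage = np.clip(row_idx + 1.0 - contour[None, :], 0.0, 1.0)
            frames[i, :, cols[0] : cols[-1] + 1] = (
                LUNG_LEVEL + (bright - LUNG_LEVEL) * coverage
            ).astype(np.float32)
    if config.pixel_noise_sd > 0:
        frames += pix.normal(0.0, config.pixel_noise_sd, frames.shape).astype(
            np.float32
        )
        np.clip(frames, 0.0, 1.0, out=frames)

    ref = h  # common elevation reference: the image bottom
    scale = (
        config.left_params.amplitude_px / config.right_params.amplitude_px
        if config.right_params.amplitude_px > 0
        else np.inf
    )
    truth = GroundTruth(
        times=times,
        left_elevation=ref - rows_l,
        right_elevation=ref - rows_r,
        true_phase_offset_deg=_wrap_signed(
            config.right_params.phase_deg - config.left_params.phase_deg
        ),
        true_amplitude_scale=scale,
        left_apex_row=rows_l,
        right_apex_row=rows_r,
        reference_row=ref,
    )
    seq = FrameSequence(frames=frames, frame_rate_hz=config.frame_rate_hz)
    return seq, truth


def _wrap_signed(deg: float) -> float:
    """Wrap a phase difference to (-180, 180]."""
    d = float(deg) % 360.0
    return d - 360.0 if d > 180.0 else d


# ---------------------------------------------------------------------------
# Canonical study scenarios
# ---------------------------------------------------------------------------

# (left A, right A, left T, right T, left-lag deg) per (name, mode).
# Quiet amplitudes/periods sit in the range measured fluoroscopically for
# an adult (domes moving ~10-25 px at ~1.9 s per breath); sniff manoeuvres
# are faster (~0.3 s) and smaller.  The weakness scenario reproduces the
# asymmetry of a weak left hemidiaphragm: ~40% of the contralateral
# amplitude with a small positive lag.  Paralysis puts the affected side
# in exact anti-phase (paradoxical motion).
_SCENARIOS: dict[tuple[str, str], tuple[float, float, float, float, float]] = {
    ("normal", "quiet"): (15.0, 15.0, 1.90, 1.90, 10.0),
    ("normal", "sniff"): (7.7, 7.7, 0.30, 0.30, 10.0),
    ("weakness", "quiet"): (9.3, 23.7, 1.92, 1.93, 18.2),
    ("weakness", "sniff"): (3.1, 7.7, 0.33, 0.33, 20.0),
    ("paralysis", "quiet"): (6.0, 15.0, 1.90, 1.90, 180.0),
    ("paralysis", "sniff"): (4.6, 7.7, 0.30, 0.30, 180.0),
}

_BASELINE_LEFT = 130.0  # chronically elevated (more cranial) left dome
_BASELINE_RIGHT = 150.0


def make_scenario(name: str, mode: str, seed: int = 0) -> SceneConfig:
    """Build the canonical scene for a named motion pattern.

    ``name`` is one of ``normal`` (symmetric amplitudes, lag < 20 deg),
    ``weakness`` (one side reduced to 30-50% with a small lag) or
    ``paralysis`` (affected side in 180 deg anti-phase); ``mode`` selects
    quiet breathing (~1.9 s period, 8 s acquisition) or the sniff
    manoeuvre (~0.3 s period, 3 s acquisition).
    """
    if name not in SCENARIO_NAMES:
        raise InvalidParameterError(
            f"unknown scenario name {name!r}; expected one of {SCENARIO_NAMES}"
        )
    if mode not in SCENARIO_MODES:
        raise InvalidParameterError(
            f"unknown scenario mode {mode!r}; expected one of {SCENARIO_MODES}"
        )
    a_l, a_r, t_l, t_r, lag_deg = _SCENARIOS[(name, mode)]
    # Positive lag = left (non-reference) lags right: phase_L = phase_R - lag.
    left = MotionParams(
        amplitude_px=a_l,
        period_s=t_l,
        phase_deg=-lag_deg,
        baseline_row=_BASELINE_LEFT,
    )
    right = MotionParams(
        amplitude_px=a_r, period_s=t_r, phase_deg=0.0, baseline_row=_BASELINE_RIGHT
    )
    return SceneConfig(
        left_params=left,
        right_params=right,
        duration_s=8.0 if mode == "quiet" else 3.0,
        seed=seed,
    )


def save_scenario(
    config: SceneConfig, out_dir: str | Path, fmt: str = "tiff"
) -> tuple[FrameSequence, GroundTruth]:
    """Render a scenario and write frames, ground-truth CSV and config JSON."""
    from .frameio import write_frames  # local import: frameio is I/O-only

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seq, truth = render_frames(config)
    write_frames(seq, out / ("frames.tif" if fmt == "tiff" else "frames"), fmt=fmt)
    truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
    (out / "scenario.json").write_text(json.dumps(config.to_dict(), indent=2))
    return seq, truth
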
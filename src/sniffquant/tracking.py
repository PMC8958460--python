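"""Per-frame dome elevation tracking.

Clinically, the height of each hemidiaphragmatic dome is read off every
fluoroscopy frame and plotted over time.  This module automates that
reading: Canny edge detection delineates the bright/dark boundary at the
lung base, and within each hemidiaphragm's region of interest the most
cranial pixel of the largest connected edge component is taken as the
dome apex.  An expert can still override individual frames via manual
picks, which are passed through verbatim.

Conventions (pinned so results are bit-reproducible):

* coordinates are 0-based and row-major; rows increase caudally
  (downward), so the dome apex is the *minimum* row of the contour;
* ROIs are half-open rectangles ``(row_min, row_max, col_min, col_max)``;
* elevation = ``reference_row - apex_row``: ascent (cranial motion) is
  positive;
* frames where no edge falls inside the ROI yield NaN samples — gaps are
  retained, never interpolated here (smoothing handles them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import feature, measure

from .errors import InvalidParameterError, TrackingError

__all__ = [
    "FrameSequence",
    "Roi",
    "RoiPair",
    "TrajectorySeries",
    "CannyParams",
    "detect_edges",
    "apex_pixel",
    "extract_dome_elevation",
    "track_sequence",
    "read_overrides",
]

#: Maximum tolerated fraction of frames without a usable edge per side.
MAX_MISSING_FRACTION = 0.25


@dataclass
class FrameSequence:
    """Ordered grayscale frames with acquisition geometry.

    ``frames`` is an ``(n_frames, height, width)`` float array with
    intensities in [0, 1].  ``pixel_spacing`` (mm/px), when known, lets
    reports quote millimetres alongside pixels.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_spacing: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be (n_frames, height, width)")
        if not self.frame_rate_hz > 0:
            raise InvalidParameterError("frame_rate_hz must be > 0")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.frame_rate_hz


@dataclass(frozen=True)
class Roi:
    """Half-open rectangle ``[row_min, row_max) x [col_min, col_max)``."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_min < self.row_max and self.col_min < self.col_max):
            raise InvalidParameterError(f"empty ROI {self}")
        if min(self.row_min, self.col_min) < 0:
            raise InvalidParameterError(f"ROI has negative bounds: {self}")

    def validate_for(self, shape: tuple[int, int]) -> None:
        if self.row_max > shape[0] or self.col_max > shape[1]:
            raise InvalidParameterError(f"ROI {self} exceeds image shape {shape}")


@dataclass(frozen=True)
class RoiPair:
    left: Roi
    right: Roi

    def __post_init__(self) -> None:
        disjoint = (
            self.left.col_max <= self.right.col_min
            or self.right.col_max <= self.left.col_min
        )
        if not disjoint:
            raise InvalidParameterError("left/right ROIs must not overlap in columns")

    @classmethod
    def split_halves(cls, shape: tuple[int, int]) -> "RoiPair":
        """Default ROIs: the left and right image halves."""
        h, w = shape
        return cls(Roi(0, h, 0, w // 2), Roi(0, h, w // 2, w))


@dataclass
class TrajectorySeries:
    """One dome-elevation sample per frame for a single side.

    Missing frames carry NaN elevation; they are flagged, never dropped,
    so downstream smoothing sees the true sampling pattern.
    """

    times: np.ndarray
    elevation: np.ndarray
    side: str = "left"
    source: str = "auto"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.times.shape != self.elevation.shape:
            raise InvalidParameterError("times and elevation must share length")
        if self.side not in ("left", "right"):
            raise InvalidParameterError("side must be 'left' or 'right'")
        if self.source not in ("auto", "manual", "synthetic"):
            raise InvalidParameterError("source must be auto, manual or synthetic")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.elevation)

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def dropna(self) -> tuple[np.ndarray, np.ndarray]:
        ok = ~self.missing
        return self.times[ok], self.elevation[ok]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "elevation_px": self.elevation,
                "side": self.side,
                "source": self.source,
            }
        )


@dataclass(frozen=True)
class CannyParams:
    """Canny settings; thresholds are fractions of the max gradient magnitude."""

    sigma: float = 2.0
    low_frac: float = 0.1
    high_frac: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.low_frac < self.high_frac <= 1:
            raise InvalidParameterError("need 0 < low_frac < high_frac <= 1")
        if not self.sigma > 0:
            raise InvalidParameterError("sigma must be > 0")


def detect_edges(
    frame: np.ndarray,
    low_frac: float = 0.1,
    high_frac: float = 0.2,
    sigma: float = 2.0,
) -> np.ndarray:
    """Canny edge map with hysteresis thresholds scaled to the frame.

    The low/high thresholds are ``low_frac``/``high_frac`` times the
    maximum Sobel gradient magnitude of the Gaussian-smoothed frame, so
    the same fractions work across exposure levels.  A constant frame
    has no gradient and yields an all-false map (not an error).
    """
    CannyParams(sigma=sigma, low_frac=low_frac, high_frac=high_frac)
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise InvalidParameterError("frame must be 2-D grayscale")
    smoothed = ndi.gaussian_filter(frame, sigma, mode="nearest")
    grad = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    gmax = float(grad.max())
    if gmax == 0.0:
        return np.zeros(frame.shape, dtype=bool)
    return feature.canny(
        frame,
        sigma=sigma,
        low_threshold=low_frac * gmax,
        high_threshold=high_frac * gmax,
    )


def apex_pixel(edge_map: np.ndarray, roi: Roi) -> Optional[tuple[int, int]]:
    """Locate the dome apex pixel inside a ROI, or None when no edge exists.

    Rule (replacing the manual pixel pick with a reproducible one): among
    edge pixels inside the ROI, keep the largest 8-connected component;
    its minimum row is the apex row, and of the pixels sharing that row
    the lower-median column is taken.  Returns absolute (row, col).
    """
    roi.validate_for(edge_map.shape)
    sub = np.asarray(edge_map, dtype=bool)[
        roi.row_min : roi.row_max, roi.col_min : roi.col_max
    ]
    if not sub.any():
        return None
    labels = measure.label(sub, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(counts.argmax())  # ties -> smallest label id (deterministic)
    rows, cols = np.nonzero(labels == best)
    rmin = int(rows.min())
    tie_cols = np.sort(cols[rows == rmin])
    col = int(tie_cols[(len(tie_cols) - 1) // 2])  # lower median
    return roi.row_min + rmin, roi.col_min + col


def extract_dome_elevation(
    edge_map: np.ndarray,
    roi: Roi,
    reference_row: int,
) -> Optional[float]:
    """Dome elevation ``reference_row - apex_row``, or None (missing sample)."""
    pix = apex_pixel(edge_map, roi)
    if pix is None:
        return None
    return float(reference_row - pix[0])


def track_sequence(
    seq: FrameSequence,
    rois: RoiPair,
    overrides: Optional[Mapping[tuple[int, str], tuple[int, int]]] = None,
    canny: CannyParams = CannyParams(),
    reference_row: Optional[int] = None,
) -> tuple[TrajectorySeries, TrajectorySeries]:
    """Track both dome elevations across a frame sequence.

    ``overrides`` maps ``(frame_index, side)`` to a manually picked
    ``(row, col)`` pixel; those samples bypass edge detection entirely.
    Deterministic: same frames and settings give identical series.

    Raises
    ------
    TrackingError
        If more than 25% of frames on either side have no usable edge.
    """
    h, _ = seq.shape
    rois.left.validate_for(seq.shape)
    rois.right.validate_for(seq.shape)
    ref = h if reference_row is None else int(reference_row)
    overrides = dict(overrides or {})

    times = seq.times()
    elev = {"left": np.full(len(seq), np.nan), "right": np.full(len(seq), np.nan)}
    manual = {"left": False, "right": False}
    roi_of = {"left": rois.left, "right": rois.right}

    for i in range(len(seq)):
        pending = [s for s in ("left", "right") if (i, s) not in overrides]
        if pending:
            edges = detect_edges(
                seq.frames[i], canny.low_frac, canny.high_frac, canny.sigma
            )
            for s in pending:
                sample = extract_dome_elevation(edges, roi_of[s], ref)
                if sample is not None:
                    elev[s][i] = sample
        for s in ("left", "right"):
            if (i, s) in overrides:
                row, _col = overrides[(i, s)]
                elev[s][i] = float(ref - row)
                manual[s] = True

    out = []
    for s in ("left", "right"):
        missing = np.mean(~np.isfinite(elev[s]))
        if missing > MAX_MISSING_FRACTION:
            raise TrackingError(
                f"{s} side: {missing:.0%} of frames have no usable edge "
                f"(limit {MAX_MISSING_FRACTION:.0%})"
            )
        out.append(
            TrajectorySeries(
                times=times,
                elevation=elev[s],
                side=s,
                source="manual" if manual[s] else "auto",
            )
        )
    return out[0], out[1]


def read_overrides(path: str | Path) -> dict[tuple[int, str], tuple[int, int]]:
    """Load manual dome picks from CSV (columns frame_index, side, row, col)."""
    df = pd.read_csv(path)
    required = {"frame_index", "side", "row", "col"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(f"overrides CSV needs columns {sorted(required)}")
    return {
        (int(r.frame_index), str(r.side)): (int(r.row), int(r.col))
        for r in df.itertuples()
    }
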
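"""Sinusoid parameters, peak/trough matching, and between-side phase/scale.

Diaphragm elevation over a breathing or sniffing window is modelled as a
single sinusoid ``A*sin(2*pi*t/T + phi) + c`` fitted by least squares
(frequency initialised from the dominant discrete-Fourier peak).  The
two hemidiaphragms are then compared by detecting peaks and troughs of
each smoothed trajectory, pairing them across sides, and estimating

* the time delay (least-squares time shift over matched pairs, handled
  on the circle so exact anti-phase does not cancel to zero), converted
  to a phase offset in degrees via the non-reference side's period; and
* the amplitude scale (least-squares ratio of extremum excursions about
  each side's mean), reported as a fraction of the reference side.

Uncertainties come from repeating the whole comparison on paired GP
posterior draws and reporting the mean +/- SD across draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.optimize import least_squares

from .errors import (
    DegenerateSignalError,
    InvalidParameterError,
    MatchingError,
    UnstableEstimateError,
)
from .gp import SmoothedTrajectory

__all__ = [
    "SinusoidFit",
    "ExtremaSet",
    "MatchedExtrema",
    "PhaseScaleEstimate",
    "fit_sinusoid",
    "find_extrema",
    "match_extrema",
    "estimate_offset_scale",
    "draw_parameter_stats",
    "summarize_fit",
    "phase_to_delay",
    "wrap_signed_deg",
    "circular_distance_deg",
]

DEFAULT_MIN_PROMINENCE_PX = 0.5
DEFAULT_N_DRAWS = 500
#: Spectral peak must exceed this multiple of the median non-DC power.
SPECTRAL_PEAK_FACTOR = 8.0


def wrap_signed_deg(deg) -> np.ndarray | float:
    """Wrap angles in degrees to (-180, 180]."""
    d = np.asarray(deg, dtype=float) % 360.0
    out = np.where(d > 180.0, d - 360.0, d)
    return float(out) if np.isscalar(deg) or out.ndim == 0 else out


def circular_distance_deg(a: float, b: float) -> float:
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _circular_mean_deg(deg: np.ndarray) -> float:
    rad = np.radians(deg)
    return math.degrees(
        math.atan2(float(np.mean(np.sin(rad))), float(np.mean(np.cos(rad))))
    )


def _circular_summary_deg(deg: np.ndarray) -> tuple[float, float]:
    """Mean and SD of angles, computed about the circular mean."""
    m = _circular_mean_deg(deg)
    dev = wrap_signed_deg(np.asarray(deg, dtype=float) - m)
    sd = float(np.std(dev, ddof=1)) if len(deg) > 1 else 0.0
    return wrap_signed_deg(m), sd


# ---------------------------------------------------------------------------
# Sinusoid fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SinusoidFit:
    """Least-squares sinusoid ``amplitude*sin(2*pi*t/period + phase) + offset``.

    ``*_sd`` fields are Monte-Carlo SDs over GP posterior draws when the
    fit was summarised across draws; None for a single-series fit.
    """

    amplitude: float  # px, >= 0
    period_s: float  # s, > 0
    phase_deg: float  # [0, 360)
    offset: float  # px
    rss: float  # px^2
    amplitude_sd: Optional[float] = None
    period_sd: Optional[float] = None
    phase_sd: Optional[float] = None
    n_draws: Optional[int] = None

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.period_s <= 0:
            raise InvalidParameterError("amplitude must be >= 0 and period > 0")
        object.__setattr__(self, "phase_deg", float(self.phase_deg) % 360.0)

    @property
    def frequency_hz(self) -> float:
        return 1.0 / self.period_s

    def __call__(self, times: np.ndarray) -> np.ndarray:
        return self.amplitude * np.sin(
            2.0 * np.pi * np.asarray(times, float) / self.period_s
            + math.radians(self.phase_deg)
        ) + self.offset

    def to_dict(self) -> dict:
        return {
            "amplitude_px": self.amplitude,
            "amplitude_sd_px": self.amplitude_sd,
            "period_s": self.period_s,
            "period_sd_s": self.period_sd,
            "phase_deg": self.phase_deg,
            "phase_sd_deg": self.phase_sd,
            "offset_px": self.offset,
            "rss_px2": self.rss,
            "n_draws": self.n_draws,
        }


def _dominant_frequency(times: np.ndarray, values: np.ndarray) -> float:
    """Frequency of the dominant spectral peak, or raise if the spectrum is flat.

    Uses the FFT periodogram on uniform sampling (with parabolic peak
    interpolation) and the Lomb-Scargle periodogram when gaps make the
    sampling non-uniform.
    """
    yc = values - values.mean()
    if float(np.std(yc)) == 0.0:
        raise DegenerateSignalError("constant series has no dominant frequency")
    dt = np.diff(times)
    uniform = np.allclose(dt, dt[0], rtol=1e-6, atol=0.0)
    if uniform:
        power = np.abs(np.fft.rfft(yc)) ** 2
        freqs = np.fft.rfftfreq(len(yc), d=float(dt[0]))
        power, freqs = power[1:], freqs[1:]
    else:
        span = float(times[-1] - times[0])
        fmax = 0.5 / float(np.min(dt))
        freqs = np.linspace(1.0 / span, fmax, 2000)
        power = sps.lombscargle(times, yc, 2.0 * np.pi * freqs)
    k = int(np.argmax(power))
    if power[k] < SPECTRAL_PEAK_FACTOR * float(np.median(power)):
        raise DegenerateSignalError(
            "no dominant spectral peak (flat spectrum); cannot fit a sinusoid"
        )
    if uniform and 0 < k < len(power) - 1:
        # parabolic interpolation of the peak bin for off-grid frequencies
        pl, pc, pr = power[k - 1 : k + 2]
        denom = pl - 2.0 * pc + pr
        shift = 0.5 * (pl - pr) / denom if denom != 0 else 0.0
        return float(freqs[k] + shift * (freqs[1] - freqs[0]))
    return float(freqs[k])


def _linear_sinusoid(times: np.ndarray, values: np.ndarray, freq: float):
    """Solve a, b, c in ``a*sin + b*cos + c`` for a fixed frequency."""
    w = 2.0 * np.pi * freq * times
    x = np.column_stack([np.sin(w), np.cos(w), np.ones_like(times)])
    coef, *_ = np.linalg.lstsq(x, values, rcond=None)
    return coef


def fit_sinusoid(times: np.ndarray, values: np.ndarray) -> SinusoidFit:
    """Fit ``A*sin(2*pi*t/T + phi) + c`` by nonlinear least squares.

    The frequency is initialised from the dominant spectral peak and all
    four parameters are refined jointly.  A is reported non-negative with
    the sign absorbed into the phase.  Requires >= 8 samples (two full
    periods of data are recommended for a stable period estimate).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 1:
        raise InvalidParameterError("times and values must be equal-length vectors")
    if len(times) < 8:
        raise InvalidParameterError("need >= 8 samples to fit a sinusoid")
    if not np.all(np.isfinite(values)):
        raise InvalidParameterError("values must be finite (drop gaps first)")

    f0 = _dominant_frequency(times, values)
    a0, b0, c0 = _linear_sinusoid(times, values, f0)
    span = float(times[-1] - times[0])
    f_lo, f_hi = 0.5 / span, 0.45 / float(np.min(np.diff(times)))

    def residual(p):
        a, b, f, c = p
        w = 2.0 * np.pi * f * times
        return a * np.sin(w) + b * np.cos(w) + c - values

    def jac(p):
        a, b, f, c = p
        w = 2.0 * np.pi * f * times
        s, co = np.sin(w), np.cos(w)
        return np.column_stack(
            [s, co, 2.0 * np.pi * times * (a * co - b * s), np.ones_like(times)]
        )

    res = least_squares(
        residual,
        x0=[a0, b0, np.clip(f0, f_lo, f_hi), c0],
        jac=jac,
        bounds=([-np.inf, -np.inf, f_lo, -np.inf], [np.inf, np.inf, f_hi, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    a, b, f, c = res.x
    return SinusoidFit(
        amplitude=float(np.hypot(a, b)),
        period_s=float(1.0 / f),
        phase_deg=math.degrees(math.atan2(b, a)) % 360.0,
        offset=float(c),
        rss=float(np.sum(res.fun**2)),
    )


# ---------------------------------------------------------------------------
# Extrema detection and matching
# ---------------------------------------------------------------------------


@dataclass
class ExtremaSet:
    """Alternating peaks and troughs of one smoothed trajectory.

    Empty arrays signal "no motion detected" at the requested prominence.
    """

    peak_times: np.ndarray
    trough_times: np.ndarray
    peak_values: np.ndarray
    trough_values: np.ndarray

    @property
    def empty(self) -> bool:
        return len(self.peak_times) == 0 and len(self.trough_times) == 0

    @property
    def n_cycles(self) -> int:
        """Respiratory cycles represented: min(#peaks, #troughs)."""
        return min(len(self.peak_times), len(self.trough_times))


def _extrema_of(
    values: np.ndarray, grid: np.ndarray, min_prominence_px: float
) -> ExtremaSet:
    pk, _ = sps.find_peaks(values, prominence=min_prominence_px)
    tr, _ = sps.find_peaks(-values, prominence=min_prominence_px)
    events = sorted(
        [(grid[i], values[i], +1) for i in pk] + [(grid[i], values[i], -1) for i in tr]
    )
    # Enforce alternation: of consecutive same-type extrema keep the more
    # extreme one (higher peak / lower trough; ties -> the earlier).
    kept: list[tuple[float, float, int]] = []
    for ev in events:
        if kept and kept[-1][2] == ev[2]:
            if ev[2] * ev[1] > ev[2] * kept[-1][1]:
                kept[-1] = ev
        else:
            kept.append(ev)
    peaks = [(t, v) for t, v, k in kept if k == +1]
    troughs = [(t, v) for t, v, k in kept if k == -1]
    return ExtremaSet(
        peak_times=np.array([t for t, _ in peaks]),
        trough_times=np.array([t for t, _ in troughs]),
        peak_values=np.array([v for _, v in peaks]),
        trough_values=np.array([v for _, v in troughs]),
    )


def find_extrema(
    smoothed: SmoothedTrajectory,
    min_prominence_px: float = DEFAULT_MIN_PROMINENCE_PX,
) -> ExtremaSet:
    """Peaks/troughs of the posterior mean with the given prominence.

    The default prominence (0.5 px) sits below any plausible dome motion
    but above residual wiggle left after GP smoothing.  An empty result
    is the no-motion flag, not an error.
    """
    if not min_prominence_px > 0:
        raise InvalidParameterError("min_prominence_px must be > 0")
    if not np.all(np.isfinite(smoothed.mean)):
        raise InvalidParameterError("smoothed mean must be finite")
    return _extrema_of(smoothed.mean, smoothed.grid_times, min_prominence_px)


@dataclass
class MatchedExtrema:
    """One-to-one pairs of same-type extrema across the two sides."""

    kinds: list[str]  # "peak" | "trough", per pair
    left_times: np.ndarray
    right_times: np.ndarray
    left_values: np.ndarray
    right_values: np.ndarray

    def __len__(self) -> int:
        return len(self.kinds)


def match_extrema(
    left: ExtremaSet, right: ExtremaSet, max_lag_s: float
) -> MatchedExtrema:
    """Greedily pair each left extremum with its nearest-in-time right
    extremum of the same type within ``max_lag_s``.

    Matching is one-to-one, nearest-first, with ties broken toward the
    earlier left extremum; unmatched extrema are dropped.  Raises
    MatchingError when no pair exists.
    """
    if left.empty or right.empty:
        raise InvalidParameterError("both extrema sets must be non-empty")
    kinds, lt, rt, lv, rv = [], [], [], [], []
    for kind, tl_all, vl_all, tr_all, vr_all in (
        ("peak", left.peak_times, left.peak_values, right.peak_times, right.peak_values),
        (
            "trough",
            left.trough_times,
            left.trough_values,
            right.trough_times,
            right.trough_values,
        ),
    ):
        cands = [
            (abs(tl_all[i] - tr_all[j]), tl_all[i], i, j)
            for i in range(len(tl_all))
            for j in range(len(tr_all))
            if abs(tl_all[i] - tr_all[j]) <= max_lag_s
        ]
        used_l: set[int] = set()
        used_r: set[int] = set()
        for _, _, i, j in sorted(cands):
            if i in used_l or j in used_r:
                continue
            used_l.add(i)
            used_r.add(j)
            kinds.append(kind)
            lt.append(tl_all[i])
            rt.append(tr_all[j])
            lv.append(vl_all[i])
            rv.append(vr_all[j])
    if not kinds:
        raise MatchingError(f"no extrema pairs within max_lag_s={max_lag_s}")
    order = np.argsort(lt)
    return MatchedExtrema(
        kinds=[kinds[i] for i in order],
        left_times=np.array(lt)[order],
        right_times=np.array(rt)[order],
        left_values=np.array(lv)[order],
        right_values=np.array(rv)[order],
    )


# ---------------------------------------------------------------------------
# Between-side phase offset and amplitude scale
# ---------------------------------------------------------------------------


@dataclass
class PhaseScaleEstimate:
    """Between-side comparison: phase offset, time delay, amplitude scale.

    Sign convention: a positive phase offset means the non-reference
    side *lags* the reference side.  ``amplitude_scale`` is the
    non-reference excursion as a fraction of the reference side.
    Uncertainties are SDs across GP posterior draws.
    """

    phase_offset_deg: float
    phase_offset_sd: float
    time_delay_s: float
    time_delay_sd: float
    amplitude_scale: float
    amplitude_scale_sd: float
    period_s: float  # non-reference period used for deg <-> s conversion
    reference: str
    n_draws: int
    n_failed: int = 0
    sinusoid_phase_diff_deg: Optional[float] = None  # cross-check diagnostic

    @property
    def amplitude_scale_pct(self) -> float:
        return 100.0 * self.amplitude_scale

    def to_dict(self) -> dict:
        return {
            "phase_offset_deg": self.phase_offset_deg,
            "phase_offset_sd_deg": self.phase_offset_sd,
            "time_delay_s": self.time_delay_s,
            "time_delay_sd_s": self.time_delay_sd,
            "amplitude_scale_pct": self.amplitude_scale_pct,
            "amplitude_scale_sd_pct": 100.0 * self.amplitude_scale_sd,
            "conversion_period_s": self.period_s,
            "reference_side": self.reference,
            "n_draws": self.n_draws,
            "n_failed_draws": self.n_failed,
            "sinusoid_phase_diff_deg": self.sinusoid_phase_diff_deg,
        }


def _draw_offset_scale(
    nonref: np.ndarray,
    ref: np.ndarray,
    grid: np.ndarray,
    period_s: float,
    max_lag_s: float,
    min_prominence_px: float,
) -> Optional[tuple[float, float]]:
    """Phase offset (deg) and scale for one paired draw, or None on failure."""
    ex_n = _extrema_of(nonref, grid, min_prominence_px)
    ex_r = _extrema_of(ref, grid, min_prominence_px)
    if ex_n.empty or ex_r.empty:
        return None
    try:
        pairs = match_extrema(ex_n, ex_r, max_lag_s)
    except MatchingError:
        return None
    # Least-squares time shift = mean pair lag, taken on the circle so
    # that exact anti-phase (+T/2 vs -T/2 pairings) does not cancel out.
    lags = pairs.left_times - pairs.right_times  # positive: non-ref lags ref
    angles = 360.0 * lags / period_s
    offset, _ = _circular_summary_deg(angles)
    exc_n = np.abs(pairs.left_values - float(np.mean(nonref)))
    exc_r = np.abs(pairs.right_values - float(np.mean(ref)))
    denom = float(np.sum(exc_r**2))
    if denom == 0.0:
        return None
    return offset, float(np.sum(exc_n * exc_r) / denom)


def estimate_offset_scale(
    left_draws: np.ndarray,
    right_draws: np.ndarray,
    grid: np.ndarray,
    reference: str = "right",
    period_s: Optional[float] = None,
    max_lag_s: Optional[float] = None,
    min_prominence_px: float = DEFAULT_MIN_PROMINENCE_PX,
) -> PhaseScaleEstimate:
    """Phase offset and amplitude scale between the two sides.

    Every paired posterior draw is analysed independently (detect
    extrema, match, estimate shift and excursion ratio); the estimate
    and its SD are the mean and SD across draws.  ``period_s`` defaults
    to the period of a sinusoid fitted to the non-reference side's
    draw-mean trajectory, and ``max_lag_s`` to half that period.

    Raises UnstableEstimateError when matching fails in more than half
    of the draws.
    """
    left_draws = np.atleast_2d(np.asarray(left_draws, dtype=float))
    right_draws = np.atleast_2d(np.asarray(right_draws, dtype=float))
    if left_draws.shape != right_draws.shape:
        raise InvalidParameterError("draw matrices must share shape")
    if reference not in ("left", "right"):
        raise InvalidParameterError("reference must be 'left' or 'right'")
    nonref_draws = left_draws if reference == "right" else right_draws
    ref_draws = right_draws if reference == "right" else left_draws
    if period_s is None:
        period_s = fit_sinusoid(grid, nonref_draws.mean(axis=0)).period_s
    if max_lag_s is None:
        max_lag_s = period_s / 2.0

    offsets, scales = [], []
    for i in range(nonref_draws.shape[0]):
        out = _draw_offset_scale(
            nonref_draws[i], ref_draws[i], grid, period_s, max_lag_s, min_prominence_px
        )
        if out is not None:
            offsets.append(out[0])
            scales.append(out[1])
    n_total = nonref_draws.shape[0]
    n_failed = n_total - len(offsets)
    if n_failed > 0.5 * n_total:
        raise UnstableEstimateError(
            f"extremum matching failed in {n_failed}/{n_total} draws"
        )
    offset_mean, offset_sd = _circular_summary_deg(np.array(offsets))
    scale_arr = np.array(scales)
    scale_sd = float(np.std(scale_arr, ddof=1)) if len(scale_arr) > 1 else 0.0
    return PhaseScaleEstimate(
        phase_offset_deg=offset_mean,
        phase_offset_sd=offset_sd,
        time_delay_s=phase_to_delay(offset_mean, period_s),
        time_delay_sd=abs(phase_to_delay(offset_sd, period_s)),
        amplitude_scale=float(np.mean(scale_arr)),
        amplitude_scale_sd=scale_sd,
        period_s=float(period_s),
        reference=reference,
        n_draws=len(offsets),
        n_failed=n_failed,
    )


def draw_parameter_stats(
    draws: np.ndarray,
    grid: np.ndarray,
    base: SinusoidFit,
    min_prominence_px: float = DEFAULT_MIN_PROMINENCE_PX,
) -> dict[str, np.ndarray]:
    """Per-draw sinusoid parameters: arrays of amplitude, period, phase, offset.

    Each draw's period comes from the mean spacing of its successive
    peaks and troughs (falling back to the base fit when a draw shows
    fewer than two same-type extrema); amplitude/phase/offset follow
    from the linear least-squares solve at that period.  Cheap enough to
    run over hundreds of draws.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    amp = np.empty(draws.shape[0])
    per = np.empty(draws.shape[0])
    pha = np.empty(draws.shape[0])
    off = np.empty(draws.shape[0])
    for i, row in enumerate(draws):
        ex = _extrema_of(row, grid, min_prominence_px)
        spacings = np.concatenate([np.diff(ex.peak_times), np.diff(ex.trough_times)])
        period = float(np.mean(spacings)) if len(spacings) else base.period_s
        a, b, c = _linear_sinusoid(grid, row, 1.0 / period)
        amp[i] = np.hypot(a, b)
        per[i] = period
        pha[i] = math.degrees(math.atan2(b, a)) % 360.0
        off[i] = c
    return {"amplitude": amp, "period": per, "phase_deg": pha, "offset": off}


def summarize_fit(base: SinusoidFit, stats: dict[str, np.ndarray]) -> SinusoidFit:
    """Attach Monte-Carlo SDs from per-draw parameter arrays to a fit."""
    _, phase_sd = _circular_summary_deg(stats["phase_deg"])
    return replace(
        base,
        amplitude_sd=float(np.std(stats["amplitude"], ddof=1)),
        period_sd=float(np.std(stats["period"], ddof=1)),
        phase_sd=phase_sd,
        n_draws=len(stats["amplitude"]),
    )


def phase_to_delay(phase_deg: float, period_s: float) -> float:
    """Convert a phase offset to a time delay: ``phase/360 * period``."""
    if not period_s > 0:
        raise InvalidParameterError("period_s must be > 0")
    return phase_deg / 360.0 * period_s
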
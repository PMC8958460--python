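"""End-to-end study orchestration: frames -> trajectories -> GP -> verdict.

``run_pipeline`` chains the stages — acquire (render a synthetic
scenario or read frames from disk), track both domes, smooth each series
with a GP, draw from the posteriors, estimate sinusoid parameters and
the between-side phase offset / amplitude scale, run the significance
tests, and classify the motion.  Everything is deterministic for a
given configuration seed, and each output embeds the configuration hash
and seed so two runs are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import compare, gp, synthetic, waveform
from .errors import (
    DegenerateSignalError,
    MatchingError,
    NoMotionError,
    SniffQuantError,
    UnstableEstimateError,
)
from .frameio import read_frames
from .tracking import (
    CannyParams,
    FrameSequence,
    RoiPair,
    TrajectorySeries,
    read_overrides,
    track_sequence,
)

__all__ = ["StudyConfig", "ReportBundle", "run_pipeline"]

log = logging.getLogger("sniffquant")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to reproduce one study analysis.

    Exactly one of ``scenario`` (``"name:mode"``, rendered synthetically)
    or ``input_path`` (frames on disk) must be given.
    """

    scenario: Optional[str] = None
    input_path: Optional[str] = None
    frame_pattern: str = "*"
    frame_rate_hz: float = 30.0
    pixel_spacing: Optional[float] = None
    rois: Optional[RoiPair] = None  # default: left/right image halves
    canny: CannyParams = field(default_factory=CannyParams)
    gp_restarts: int = 5
    grid_oversample: int = 10
    n_draws: int = waveform.DEFAULT_N_DRAWS
    min_prominence_px: float = waveform.DEFAULT_MIN_PROMINENCE_PX
    reference_side: str = "right"
    overrides_path: Optional[str] = None
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.input_path is None):
            raise SniffQuantError("give exactly one of scenario or input_path")
        if self.reference_side not in ("left", "right"):
            raise SniffQuantError("reference_side must be 'left' or 'right'")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All per-study results plus provenance (config echo, hash, seed)."""

    config: StudyConfig
    left_series: TrajectorySeries
    right_series: TrajectorySeries
    left_smoothed: gp.SmoothedTrajectory
    right_smoothed: gp.SmoothedTrajectory
    left_fit: Optional[waveform.SinusoidFit]
    right_fit: Optional[waveform.SinusoidFit]
    offset_scale: Optional[waveform.PhaseScaleEstimate]
    amplitude_test: Optional[compare.TestResult]
    frequency_test: Optional[compare.TestResult]
    paradox_test: Optional[compare.ParadoxTestResult]
    classification: compare.MotionClassification
    ground_truth: Optional[synthetic.GroundTruth] = None
    analysis_note: str = ""

    def to_dict(self) -> dict:
        def opt(x):
            return None if x is None else x.to_dict()

        d = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "n_frames": len(self.left_series),
            "left_fit": opt(self.left_fit),
            "right_fit": opt(self.right_fit),
            "phase_scale": opt(self.offset_scale),
            "amplitude_test": opt(self.amplitude_test),
            "frequency_test": opt(self.frequency_test),
            "paradox_test": opt(self.paradox_test),
            "classification": self.classification.to_dict(),
            "analysis_note": self.analysis_note,
        }
        if self.config.pixel_spacing and self.left_fit and self.right_fit:
            d["amplitude_mm"] = {
                "left": self.left_fit.amplitude * self.config.pixel_spacing,
                "right": self.right_fit.amplitude * self.config.pixel_spacing,
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, default=str)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.concat(
            [self.left_series.to_frame(), self.right_series.to_frame()]
        ).to_csv(out / "trajectories.csv", index=False)
        self.left_smoothed.to_frame().to_csv(out / "smoothed_left.csv", index=False)
        self.right_smoothed.to_frame().to_csv(out / "smoothed_right.csv", index=False)
        (out / "report.json").write_text(self.to_json())
        try:
            plot_study(self, out / "figure.png")
        except Exception as exc:  # plotting must never sink a finished study
            log.warning("figure rendering failed: %s", exc)
        return out / "report.json"


def _derived_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) for the pipeline stages."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def _stage(name: str, t0: float, detail: str) -> None:
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, detail)


def effective_cycle_count(
    left: waveform.ExtremaSet, right: waveform.ExtremaSet
) -> int:
    """Sample size for the side-to-side t-tests: observed breath cycles.

    Posterior draws are samples of *one* record, so the information
    available about between-side differences grows with the number of
    breaths observed, not with the number of draws; the draw SD enters
    as the per-cycle spread.  The count is the smaller side's complete
    cycles, floored at 2.
    """
    return max(2, min(left.n_cycles, right.n_cycles))


def run_pipeline(config: StudyConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    Returns the assembled :class:`ReportBundle`; when ``config.out_dir``
    is set the CSVs, JSON report and figure are written there as well.
    Unstable or degenerate waveform estimates downgrade the
    classification to ``indeterminate`` instead of aborting; genuine
    stage failures (I/O, tracking) propagate with the stage name.
    """
    seeds = _derived_seeds(config.seed, 5)
    t0 = time.perf_counter()

    # --- acquire -----------------------------------------------------------
    truth: Optional[synthetic.GroundTruth] = None
    if config.scenario is not None:
        try:
            name, mode = config.scenario.split(":")
        except ValueError as exc:
            raise SniffQuantError(
                f"scenario must be 'name:mode', got {config.scenario!r}"
            ) from exc
        scene = synthetic.make_scenario(name, mode, seed=seeds[0])
        seq, truth = synthetic.render_frames(scene)
    else:
        seq = read_frames(
            config.input_path,
            pattern=config.frame_pattern,
            frame_rate_hz=config.frame_rate_hz,
            pixel_spacing=config.pixel_spacing,
        )
    _stage("acquire", t0, f"n_frames={len(seq)} shape={seq.shape}")

    # --- track -------------------------------------------------------------
    t0 = time.perf_counter()
    rois = config.rois or RoiPair.split_halves(seq.shape)
    overrides = read_overrides(config.overrides_path) if config.overrides_path else None
    try:
        left, right = track_sequence(seq, rois, overrides=overrides, canny=config.canny)
    except SniffQuantError as exc:
        raise type(exc)(f"stage 'track': {exc}") from exc
    _stage(
        "track",
        t0,
        f"missing_left={left.n_missing} missing_right={right.n_missing}",
    )

    # --- smooth ------------------------------------------------------------
    t0 = time.perf_counter()
    model_l = gp.fit_gp(left, n_restarts=config.gp_restarts, seed=seeds[1])
    model_r = gp.fit_gp(right, n_restarts=config.gp_restarts, seed=seeds[2])
    grid = gp.default_grid(seq.times(), oversample=config.grid_oversample)
    smooth_l = gp.predict(model_l, grid)
    smooth_r = gp.predict(model_r, grid)
    draws_l = gp.sample_posterior(model_l, grid, config.n_draws, seed=seeds[3])
    draws_r = gp.sample_posterior(model_r, grid, config.n_draws, seed=seeds[4])
    _stage(
        "smooth",
        t0,
        f"grid={len(grid)} draws={config.n_draws} "
        f"hyp_left={model_l.hyperparams} hyp_right={model_r.hyperparams}",
    )

    # --- waveform + stats --------------------------------------------------
    t0 = time.perf_counter()
    fit_l = fit_r = est = ampl_test = freq_test = paradox = None
    note = ""
    ex_l = waveform.find_extrema(smooth_l, config.min_prominence_px)
    ex_r = waveform.find_extrema(smooth_r, config.min_prominence_px)
    motion_present = ex_l.n_cycles >= 1 and ex_r.n_cycles >= 1
    try:
        if not motion_present:
            raise NoMotionError("fewer than one full cycle on at least one side")
        fit_l = waveform.fit_sinusoid(grid, draws_l.mean(axis=0))
        fit_r = waveform.fit_sinusoid(grid, draws_r.mean(axis=0))
        stats_l = waveform.draw_parameter_stats(
            draws_l, grid, fit_l, config.min_prominence_px
        )
        stats_r = waveform.draw_parameter_stats(
            draws_r, grid, fit_r, config.min_prominence_px
        )
        fit_l = waveform.summarize_fit(fit_l, stats_l)
        fit_r = waveform.summarize_fit(fit_r, stats_r)
        nonref_fit = fit_l if config.reference_side == "right" else fit_r
        est = waveform.estimate_offset_scale(
            draws_l,
            draws_r,
            grid,
            reference=config.reference_side,
            period_s=nonref_fit.period_s,
            min_prominence_px=config.min_prominence_px,
        )
        est.sinusoid_phase_diff_deg = waveform.wrap_signed_deg(
            (fit_r if config.reference_side == "right" else fit_l).phase_deg
            - nonref_fit.phase_deg
        )
        n_eff = effective_cycle_count(ex_l, ex_r)
        ampl_test = compare.compare_params(
            float(np.mean(stats_l["amplitude"])),
            float(np.std(stats_l["amplitude"], ddof=1)),
            float(np.mean(stats_r["amplitude"])),
            float(np.std(stats_r["amplitude"], ddof=1)),
            n_eff,
            n_eff,
        )
        freq_l, freq_r = 1.0 / stats_l["period"], 1.0 / stats_r["period"]
        freq_test = compare.compare_params(
            float(np.mean(freq_l)),
            float(np.std(freq_l, ddof=1)),
            float(np.mean(freq_r)),
            float(np.std(freq_r, ddof=1)),
            n_eff,
            n_eff,
        )
        paradox = compare.test_paradoxical(est)
    except (
        NoMotionError,
        DegenerateSignalError,
        MatchingError,
        UnstableEstimateError,
    ) as exc:
        note = f"{type(exc).__name__}: {exc}"
        log.warning("waveform stage degraded to indeterminate: %s", note)
    classification = compare.classify(ampl_test, est, paradox, motion_present)
    _stage("analyze", t0, f"label={classification.label}")

    bundle = ReportBundle(
        config=config,
        left_series=left,
        right_series=right,
        left_smoothed=smooth_l,
        right_smoothed=smooth_r,
        left_fit=fit_l,
        right_fit=fit_r,
        offset_scale=est,
        amplitude_test=ampl_test,
        frequency_test=freq_test,
        paradox_test=paradox,
        classification=classification,
        ground_truth=truth,
        analysis_note=note,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def plot_study(bundle: ReportBundle, path: str | Path) -> None:
    """Both smoothed trajectories with 95% bands over the tracked samples."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    fig = Figure(figsize=(9, 4.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for series, smooth, color, name in (
        (bundle.left_series, bundle.left_smoothed, "tab:blue", "left"),
        (bundle.right_series, bundle.right_smoothed, "tab:red", "right"),
    ):
        t, y = series.dropna()
        ax.plot(t, y, ".", color=color, ms=2.5, alpha=0.4)
        ax.plot(smooth.grid_times, smooth.mean, color=color, lw=1.5, label=name)
        ax.fill_between(
            smooth.grid_times,
            smooth.ci95_low,
            smooth.ci95_high,
            color=color,
            alpha=0.2,
            lw=0,
        )
    ax.set_xlabel("time [s]")
    ax.set_ylabel("dome elevation [px]")
    ax.set_title(f"Diaphragm elevation — {bundle.classification.label}")
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
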
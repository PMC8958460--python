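"""Shared fixtures: small rendered scenes with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

import sniffquant as sq


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2**31."""
    return [
        int(c.generate_state(1)[0] % 2**31)
        for c in np.random.SeedSequence(seed).spawn(n)
    ]


def noiseless(config: sq.SceneConfig) -> sq.SceneConfig:
    from dataclasses import replace

    return replace(config, apex_jitter_sd_px=0.0, pixel_noise_sd=0.0)


@pytest.fixture(scope="session")
def quiet_scene():
    """Noiseless 4 s quiet-breathing render (asymmetric amplitudes) + truth."""
    from dataclasses import replace

    cfg = noiseless(replace(sq.make_scenario("weakness", "quiet", seed=7),
                            duration_s=4.0))
    seq, truth = sq.render_frames(cfg)
    return cfg, seq, truth


@pytest.fixture(scope="session")
def quiet_tracked(quiet_scene):
    _, seq, truth = quiet_scene
    left, right = sq.track_sequence(seq, sq.RoiPair.split_halves(seq.shape))
    return left, right, truth


@pytest.fixture(scope="session")
def paralysis_scene():
    """Noiseless 4 s render with equal amplitudes in exact anti-phase."""
    left = sq.MotionParams(
        amplitude_px=12.0, period_s=1.9, phase_deg=180.0, baseline_row=130.0
    )
    right = sq.MotionParams(
        amplitude_px=12.0, period_s=1.9, phase_deg=0.0, baseline_row=150.0
    )
    cfg = sq.SceneConfig(
        left_params=left,
        right_params=right,
        duration_s=4.0,
        seed=11,
        apex_jitter_sd_px=0.0,
        pixel_noise_sd=0.0,
    )
    return cfg, *sq.render_frames(cfg)
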
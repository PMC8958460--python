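"""GP smoothing: closed-form correctness, hyperparameter fits, draws."""

import numpy as np
import pytest

import sniffquant as sq
from sniffquant import gp
from conftest import child_seeds


def manual_model(times, values, signal_sd, length_scale, noise_sd) -> sq.GPModel:
    """Build a GPModel at fixed hyperparameters (no optimisation)."""
    return sq.GPModel(
        hyperparams=sq.GPHyperparams(signal_sd, length_scale, noise_sd),
        train_times=np.asarray(times, float),
        train_values=np.asarray(values, float),
        y_mean=float(np.mean(values)),
        log_marginal_likelihood=np.nan,
    )


def brute_force_posterior(model, grid):
    """Independent oracle: direct linear solve of the GP equations."""
    hp = model.hyperparams
    t, y = model.train_times, model.train_values - model.y_mean

    def k(a, b):
        return hp.signal_sd**2 * np.exp(
            -0.5 * ((a[:, None] - b[None, :]) / hp.length_scale) ** 2
        )

    ky = k(t, t) + (hp.noise_sd**2 + gp.JITTER_REL * hp.signal_sd**2) * np.eye(len(t))
    ks = k(np.asarray(grid, float), t)
    inv = np.linalg.inv(ky)
    mean = ks @ inv @ y + model.y_mean
    var = hp.signal_sd**2 - np.einsum("ij,jk,ik->i", ks, inv, ks)
    return mean, np.sqrt(np.maximum(var, 0))


class TestPosteriorClosedForm:
    def test_mean_and_sd_match_direct_solve(self):
        """Cholesky path equals the brute-force linear solve on 20 points."""
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(0, 5, 20))
        y = 3 * np.sin(2 * np.pi * t / 1.7) + rng.normal(0, 0.5, 20) + 100
        model = manual_model(t, y, signal_sd=3.0, length_scale=0.4, noise_sd=0.5)
        grid = np.linspace(0, 5, 57)
        sm = sq.predict(model, grid)
        mean_o, sd_o = brute_force_posterior(model, grid)
        assert np.max(np.abs(sm.mean - mean_o)) < 1e-8
        assert np.max(np.abs(sm.sd - sd_o)) < 1e-8

    def test_posterior_sd_bounded_by_prior(self):
        model = manual_model(
            np.linspace(0, 4, 30), np.sin(np.linspace(0, 4, 30)), 2.0, 0.3, 0.4
        )
        sm = sq.predict(model, np.linspace(-0.2, 4.2, 300))
        prior = np.sqrt(2.0**2 + 0.4**2)
        assert np.all(sm.sd >= 0)
        assert np.all(sm.predictive_sd <= prior + 1e-6)

    def test_far_from_data_sd_approaches_prior_level(self):
        """Inside a long gap the predictive sd returns to the prior level."""
        t = np.concatenate([np.linspace(0, 1, 12), np.linspace(20, 21, 12)])
        model = manual_model(t, np.sin(t), signal_sd=2.0, length_scale=0.3,
                             noise_sd=0.5)
        sm = sq.predict(model, np.array([10.5]))
        assert sm.predictive_sd[0] == pytest.approx(np.hypot(2.0, 0.5), rel=1e-6)
        assert sm.sd[0] == pytest.approx(2.0, rel=1e-6)

    def test_extrapolation_outside_window_rejected(self):
        model = manual_model(np.linspace(0, 4, 20), np.zeros(20), 1.0, 0.5, 0.3)
        with pytest.raises(sq.ExtrapolationError):
            sq.predict(model, np.array([5.0]))  # > max + length_scale

    def test_shrinking_noise_reduces_training_residual(self):
        """MSE at training points decreases monotonically as noise_sd shrinks."""
        rng = np.random.default_rng(3)
        t = np.linspace(0, 6, 40)
        y = 5 * np.sin(2 * np.pi * t / 1.9) + rng.normal(0, 1.0, 40)
        mses = []
        for noise in (4.0, 2.0, 1.0, 0.5, 0.25, 0.1):
            model = manual_model(t, y, 5.0, 0.4, noise)
            resid = sq.predict(model, t).mean - y
            mses.append(float(np.mean(resid**2)))
        assert all(a > b for a, b in zip(mses, mses[1:]))


class TestFitGP:
    def test_noiseless_sinusoid_interpolated(self):
        """With the noise floor lowered the posterior mean interpolates."""
        times = np.arange(0, 8, 1 / 30)
        series = sq.generate_trajectory(
            sq.MotionParams(10.0, 1.9, 0.0, 150.0), times, seed=0
        )
        bounds = gp.GPBounds.for_series(times)
        bounds = gp.GPBounds(
            signal_sd=bounds.signal_sd,
            length_scale=bounds.length_scale,
            noise_sd=(0.01, 20.0),
        )
        model = sq.fit_gp(series, seed=1, bounds=bounds)
        sm = sq.predict(model, times)
        assert np.max(np.abs(sm.mean - series.elevation)) < 0.01

    def test_pure_noise_series_fit_flat(self):
        """With no signal the GP attributes variance to noise, not structure."""
        times = np.arange(0, 10, 1 / 30)
        series = sq.generate_trajectory(
            sq.MotionParams(0.0, 1.9, 0.0, 150.0, noise_sd_px=2.0), times, seed=21
        )
        model = sq.fit_gp(series, seed=2)
        assert 1.4 <= model.hyperparams.noise_sd <= 2.8
        sm = sq.predict(model, times)
        assert np.ptp(sm.mean) < 1.0

    def test_quiet_breathing_length_scale_band(self, quiet_tracked):
        """Fitted length scale is shorter than a breath, longer than a frame."""
        left, _, _ = quiet_tracked
        model = sq.fit_gp(left, seed=3)
        assert 0.05 < model.hyperparams.length_scale < 1.92

    def test_missing_samples_excluded(self):
        times = np.arange(0, 8, 1 / 30)
        series = sq.generate_trajectory(
            sq.MotionParams(8.0, 1.9, 0.0, 150.0, noise_sd_px=0.5), times, seed=4
        )
        series.elevation[::10] = np.nan
        model = sq.fit_gp(series, seed=5)
        assert len(model.train_times) == len(times) - len(times[::10])

    def test_too_few_samples_raise(self):
        series = sq.TrajectorySeries(np.arange(5) / 30, np.zeros(5))
        with pytest.raises(sq.FitError):
            sq.fit_gp(series)


@pytest.fixture(scope="module")
def fitted():
    times = np.arange(0, 6, 1 / 30)
    series = sq.generate_trajectory(
        sq.MotionParams(10.0, 1.9, 0.0, 150.0, noise_sd_px=1.0), times, seed=8
    )
    model = sq.fit_gp(series, seed=9)
    grid = np.linspace(0, 6, 150)
    return model, grid


class TestSamplePosterior:
    def test_same_seed_identical_draws(self, fitted):
        model, grid = fitted
        a = sq.sample_posterior(model, grid, n_draws=2, seed=13)
        b = sq.sample_posterior(model, grid, n_draws=2, seed=13)
        assert np.array_equal(a, b)

    def test_draw_moments_match_posterior(self, fitted):
        """Sample mean/SD over 1000 draws agree with the analytic posterior."""
        model, grid = fitted
        draws = sq.sample_posterior(model, grid, n_draws=1000, seed=17)
        sm = sq.predict(model, grid)
        assert np.max(np.abs(draws.mean(axis=0) - sm.mean)) < 0.1
        sd = draws.std(axis=0, ddof=1)
        mask = sm.sd > 0.05  # relative check needs a non-degenerate scale
        assert np.all(np.abs(sd[mask] / sm.sd[mask] - 1) < 0.10)

    def test_fewer_than_two_draws_rejected(self, fitted):
        model, grid = fitted
        with pytest.raises(sq.InvalidParameterError):
            sq.sample_posterior(model, grid, n_draws=1, seed=0)


def test_band_coverage_calibrated():
    """95% bands cover the true noiseless curve at roughly nominal rate.

    Small replicate count here for speed; the full 200-replicate check
    lives in the acceptance suite.
    """
    rates = []
    for seed in range(20):
        s = child_seeds(seed, 2)
        times = np.arange(0, 6, 1 / 30)
        truth = sq.MotionParams(15.0, 1.9, 0.0, 150.0)
        series = sq.generate_trajectory(
            sq.MotionParams(15.0, 1.9, 0.0, 150.0, noise_sd_px=2.0),
            times,
            seed=s[0],
        )
        model = sq.fit_gp(series, n_restarts=2, seed=s[1])
        sm = sq.predict(model, times)
        clean = sq.generate_trajectory(truth, times, seed=0).elevation
        rates.append(
            np.mean((clean >= sm.ci95_low) & (clean <= sm.ci95_high))
        )
    assert 0.85 <= np.mean(rates) <= 1.0
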
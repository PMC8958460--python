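"""Gaussian-process smoothing of dome-elevation series.

The tracked elevation samples are noisy and may have gaps.  A GP with a
squared-exponential kernel,

    k(t, t') = signal_sd^2 * exp(-(t - t')^2 / (2 * length_scale^2))
               + noise_sd^2 * 1[t = t'],

models the forward/backward temporal correlation of the dome motion
together with per-sample measurement noise.  Hyperparameters are set by
maximising the log marginal likelihood (multi-restart L-BFGS in log
space, bounded; delegated to scikit-learn), after which the posterior
over the *latent* noise-free trajectory is computed in closed form:

    mean* = K*' (K + noise_sd^2 I)^-1 y
    cov*  = K** - K*' (K + noise_sd^2 I)^-1 K*

Pointwise 95% bands use the Gaussian 1.96 multiplier on the latent sd;
the noise-inclusive predictive sd is exposed separately.  Joint
posterior draws over a dense grid carry the smoothing uncertainty into
the waveform comparisons downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .errors import ExtrapolationError, FitError, InvalidParameterError
from .tracking import TrajectorySeries

__all__ = [
    "GPHyperparams",
    "GPBounds",
    "GPModel",
    "SmoothedTrajectory",
    "fit_gp",
    "predict",
    "sample_posterior",
    "default_grid",
]

#: Relative jitter added to the training-kernel diagonal for stability.
JITTER_REL = 1e-8

MIN_TRAIN_SAMPLES = 8


@dataclass(frozen=True)
class GPHyperparams:
    """SE-kernel hyperparameters: all strictly positive."""

    signal_sd: float  # px
    length_scale: float  # s
    noise_sd: float  # px

    def __post_init__(self) -> None:
        for name in ("signal_sd", "length_scale", "noise_sd"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class GPBounds:
    """Box constraints for the hyperparameter search (px / s / px).

    Defaults: signal_sd in [0.1, 100] px, noise_sd in [0.05, 20] px, and
    length_scale between two frame intervals and the record duration.
    """

    signal_sd: tuple[float, float] = (0.1, 100.0)
    length_scale: tuple[float, float] = (1e-3, 1e3)
    noise_sd: tuple[float, float] = (0.05, 20.0)

    @classmethod
    def for_series(cls, times: np.ndarray) -> "GPBounds":
        dt = float(np.median(np.diff(times)))
        duration = float(times[-1] - times[0])
        return cls(length_scale=(2.0 * dt, max(duration, 4.0 * dt)))


def _se_cov(ta: np.ndarray, tb: np.ndarray, hp: GPHyperparams) -> np.ndarray:
    d = ta[:, None] - tb[None, :]
    return hp.signal_sd**2 * np.exp(-0.5 * (d / hp.length_scale) ** 2)


@dataclass
class GPModel:
    """A fitted GP: hyperparameters plus cached training factorisation."""

    hyperparams: GPHyperparams
    train_times: np.ndarray
    train_values: np.ndarray
    y_mean: float
    log_marginal_likelihood: float
    _cho: tuple = field(default=None, repr=False)
    _alpha: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._cho is None:
            k = _se_cov(self.train_times, self.train_times, self.hyperparams)
            k[np.diag_indices_from(k)] += (
                self.hyperparams.noise_sd**2
                + JITTER_REL * self.hyperparams.signal_sd**2
            )
            self._cho = cho_factor(k, lower=True)
            self._alpha = cho_solve(self._cho, self.train_values - self.y_mean)

    @property
    def window(self) -> tuple[float, float]:
        """Allowed prediction window: data span padded by one length scale."""
        ell = self.hyperparams.length_scale
        return float(self.train_times.min() - ell), float(self.train_times.max() + ell)


@dataclass
class SmoothedTrajectory:
    """GP posterior over a dense time grid.

    ``sd`` is the latent (noise-free) function sd, from which the
    pointwise 95% band is built; ``predictive_sd`` additionally includes
    the fitted measurement noise and tends to the prior level
    ``sqrt(signal_sd^2 + noise_sd^2)`` far from any datum.
    """

    grid_times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    predictive_sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid_times) <= 0):
            raise InvalidParameterError("grid_times must be strictly increasing")
        if np.any(self.sd < 0):
            raise InvalidParameterError("sd must be non-negative")

    @property
    def ci95_low(self) -> np.ndarray:
        return self.mean - 1.96 * self.sd

    @property
    def ci95_high(self) -> np.ndarray:
        return self.mean + 1.96 * self.sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.grid_times,
                "mean_px": self.mean,
                "sd_px": self.sd,
                "ci_low": self.ci95_low,
                "ci_high": self.ci95_high,
            }
        )


def fit_gp(
    series: TrajectorySeries,
    init: Optional[GPHyperparams] = None,
    n_restarts: int = 5,
    seed: int = 0,
    bounds: Optional[GPBounds] = None,
) -> GPModel:
    """Fit SE-kernel hyperparameters by maximum marginal likelihood.

    Missing (NaN) samples are excluded from training.  ``n_restarts``
    extra optimiser starts are drawn log-uniformly inside ``bounds``
    (deterministic for a given seed).  Requires >= 8 usable samples.
    """
    t, y = series.dropna()
    if len(t) < MIN_TRAIN_SAMPLES:
        raise FitError(
            f"need >= {MIN_TRAIN_SAMPLES} non-missing samples, got {len(t)}"
        )
    if bounds is None:
        bounds = GPBounds.for_series(t)
    y_mean = float(np.mean(y))
    yc = y - y_mean
    sd0 = float(np.std(yc))

    def clip(v: float, lohi: tuple[float, float]) -> float:
        return float(np.clip(v, *lohi))

    if init is None:
        span = float(t[-1] - t[0])
        init = GPHyperparams(
            signal_sd=clip(max(sd0, 0.2), bounds.signal_sd),
            length_scale=clip(span / 10.0, bounds.length_scale),
            noise_sd=clip(max(0.25 * sd0, 0.1), bounds.noise_sd),
        )

    sq = lambda lohi: (lohi[0] ** 2, lohi[1] ** 2)  # noqa: E731
    kernel = ConstantKernel(
        init.signal_sd**2, constant_value_bounds=sq(bounds.signal_sd)
    ) * RBF(init.length_scale, length_scale_bounds=bounds.length_scale) + WhiteKernel(
        init.noise_sd**2, noise_level_bounds=sq(bounds.noise_sd)
    )
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        alpha=JITTER_REL * init.signal_sd**2,
        n_restarts_optimizer=n_restarts,
        normalize_y=False,
        random_state=seed % 2**31,
    )
    try:
        with warnings.catch_warnings():
            # Optima pinned at a bound are legitimate here (bounds are part
            # of the model); silence the advisory.
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(t[:, None], yc)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FitError(f"marginal-likelihood optimisation failed: {exc}") from exc

    k = gpr.kernel_
    hp = GPHyperparams(
        signal_sd=float(np.sqrt(k.k1.k1.constant_value)),
        length_scale=float(k.k1.k2.length_scale),
        noise_sd=float(np.sqrt(k.k2.noise_level)),
    )
    return GPModel(
        hyperparams=hp,
        train_times=t,
        train_values=y,
        y_mean=y_mean,
        log_marginal_likelihood=float(gpr.log_marginal_likelihood_value_),
    )


def _latent(model: GPModel, grid: np.ndarray, want_cov: bool):
    hp = model.hyperparams
    ks = _se_cov(grid, model.train_times, hp)
    mean = ks @ model._alpha + model.y_mean
    lower = solve_triangular(model._cho[0], ks.T, lower=True)
    if want_cov:
        cov = _se_cov(grid, grid, hp) - lower.T @ lower
        return mean, cov
    var = hp.signal_sd**2 - np.einsum("ij,ij->j", lower, lower)
    return mean, np.maximum(var, 0.0)


def _check_window(model: GPModel, grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    lo, hi = model.window
    if grid.min() < lo or grid.max() > hi:
        raise ExtrapolationError(
            f"grid [{grid.min():.3f}, {grid.max():.3f}] s exceeds the allowed "
            f"window [{lo:.3f}, {hi:.3f}] s (data span +/- one length scale)"
        )
    return grid


def predict(model: GPModel, grid_times: np.ndarray) -> SmoothedTrajectory:
    """Posterior mean and pointwise sd on a grid inside the allowed window."""
    grid = _check_window(model, grid_times)
    mean, var = _latent(model, grid, want_cov=False)
    sd = np.sqrt(var)
    pred_sd = np.sqrt(var + model.hyperparams.noise_sd**2)
    return SmoothedTrajectory(grid_times=grid, mean=mean, sd=sd, predictive_sd=pred_sd)


def sample_posterior(
    model: GPModel,
    grid_times: np.ndarray,
    n_draws: int,
    seed: int = 0,
) -> np.ndarray:
    """Joint draws of the latent trajectory: an (n_draws, len(grid)) matrix.

    Deterministic for a given seed.  If the posterior covariance is not
    numerically positive definite, diagonal jitter is escalated (from
    1e-10 to 1e-4 of signal variance) before giving up.
    """
    if n_draws < 2:
        raise InvalidParameterError("n_draws must be >= 2")
    grid = _check_window(model, grid_times)
    mean, cov = _latent(model, grid, want_cov=True)
    sig2 = model.hyperparams.signal_sd**2
    chol = None
    for jit in (1e-10, 1e-8, 1e-6, 1e-4):
        try:
            chol = cholesky(cov + jit * sig2 * np.eye(len(grid)), lower=True)
            break
        except np.linalg.LinAlgError:
            continue
    if chol is None:
        raise FitError("posterior covariance not positive definite even with jitter")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((len(grid), n_draws))
    return (mean[:, None] + chol @ z).T


def default_grid(times: np.ndarray, oversample: int = 10) -> np.ndarray:
    """Dense prediction grid: ``oversample`` points per frame interval.

    The default (10x) resolves the peaks of the fast sniff signal
    (~0.3 s period at 30 frames/s).
    """
    times = np.asarray(times, dtype=float)
    dt = float(np.median(np.diff(times)))
    n = int(round((times[-1] - times[0]) / (dt / oversample))) + 1
    return np.linspace(times[0], times[-1], n)
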
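"""Sinusoid fitting, extrema detection/matching, phase/scale estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sniffquant as sq
from sniffquant import waveform
from sniffquant.gp import SmoothedTrajectory


def smoothed(grid, mean):
    z = np.zeros_like(np.asarray(mean, float))
    return SmoothedTrajectory(grid_times=grid, mean=mean, sd=z, predictive_sd=z)


class TestFitSinusoid:
    def test_exact_recovery_of_noiseless_model(self):
        t = np.arange(0, 10, 1 / 30)
        y = 5.0 * np.sin(2 * np.pi * t / 2.0) + 3.0
        fit = sq.fit_sinusoid(t, y)
        assert abs(fit.amplitude - 5.0) < 1e-6
        assert abs(fit.period_s - 2.0) < 1e-6
        assert abs(fit.offset - 3.0) < 1e-6

    def test_constant_series_degenerate(self):
        with pytest.raises(sq.DegenerateSignalError):
            sq.fit_sinusoid(np.arange(0, 2, 0.05), np.full(40, 7.0))

    def test_fit_is_idempotent_on_own_curve(self):
        t = np.arange(0, 8, 1 / 30)
        first = sq.fit_sinusoid(t, 4.2 * np.sin(2 * np.pi * t / 1.7 + 0.8) + 1.0)
        second = sq.fit_sinusoid(t, first(t))
        assert abs(second.amplitude - first.amplitude) < 1e-8
        assert abs(second.period_s - first.period_s) < 1e-8
        assert abs(second.phase_deg - first.phase_deg) < 1e-8

    def test_negative_lobe_absorbed_into_phase(self):
        t = np.arange(0, 6, 1 / 30)
        fit = sq.fit_sinusoid(t, -3.0 * np.sin(2 * np.pi * t / 1.5))
        assert fit.amplitude == pytest.approx(3.0, abs=1e-6)
        assert fit.phase_deg == pytest.approx(180.0, abs=1e-4)

    def test_noisy_recovery_median_close_to_truth(self):
        """Median over replicates recovers the quiet-breathing left side."""
        t = np.arange(0, 12, 1 / 30)
        amps, periods = [], []
        for seed in range(100):
            series = sq.generate_trajectory(
                sq.MotionParams(9.3, 1.92, 0.0, 150.0, noise_sd_px=2.0),
                t,
                seed=seed,
            )
            fit = sq.fit_sinusoid(t, series.elevation)
            amps.append(fit.amplitude)
            periods.append(fit.period_s)
        assert abs(np.median(amps) - 9.3) <= 0.5
        assert abs(np.median(periods) - 1.92) <= 0.05

    def test_amplitude_recovery_unbiased(self):
        """Mean recovered amplitude within 3% of truth across replicates."""
        t = np.arange(0, 12, 1 / 30)
        amps = [
            sq.fit_sinusoid(
                t,
                sq.generate_trajectory(
                    sq.MotionParams(9.3, 1.92, 0.0, 150.0, noise_sd_px=2.0),
                    t,
                    seed=200 + s,
                ).elevation,
            ).amplitude
            for s in range(200)
        ]
        assert 0.97 <= np.mean(amps) / 9.3 <= 1.03


class TestFindExtrema:
    def test_five_period_sinusoid_has_five_of_each(self):
        grid = np.linspace(0, 5 * 2.0, 3000, endpoint=False)
        ex = sq.find_extrema(smoothed(grid, 4 * np.sin(2 * np.pi * grid / 2.0)))
        assert len(ex.peak_times) == 5
        assert len(ex.trough_times) == 5

    def test_constant_mean_flags_no_motion(self):
        grid = np.linspace(0, 5, 500)
        ex = sq.find_extrema(smoothed(grid, np.full(500, 3.0)))
        assert ex.empty

    def test_sniff_window_peak_count(self):
        """A 3 s sniff record at T=0.3 s shows about ten peaks."""
        grid = np.linspace(0, 3, 3000, endpoint=False)
        ex = sq.find_extrema(smoothed(grid, 5 * np.sin(2 * np.pi * grid / 0.3)))
        assert abs(len(ex.peak_times) - 10) <= 1

    def test_alternation_enforced(self):
        """Peaks and troughs strictly interleave even for wiggly signals."""
        rng = np.random.default_rng(5)
        grid = np.linspace(0, 10, 2000)
        y = np.sin(2 * np.pi * grid / 2.0) + 0.4 * np.sin(2 * np.pi * grid / 0.43)
        y += 0.05 * rng.standard_normal(2000)
        ex = sq.find_extrema(smoothed(grid, y), min_prominence_px=0.05)
        events = sorted(
            [(t, +1) for t in ex.peak_times] + [(t, -1) for t in ex.trough_times]
        )
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestMatchExtrema:
    def make_set(self, peaks, troughs):
        return waveform.ExtremaSet(
            peak_times=np.asarray(peaks, float),
            trough_times=np.asarray(troughs, float),
            peak_values=np.ones(len(peaks)),
            trough_values=-np.ones(len(troughs)),
        )

    def test_identical_sets_zero_lag(self):
        a = self.make_set([1, 3, 5], [2, 4])
        pairs = sq.match_extrema(a, a, max_lag_s=1.0)
        assert len(pairs) == 5
        assert np.allclose(pairs.left_times, pairs.right_times)

    def test_uniform_shift_recovered(self):
        left = self.make_set([1, 3, 5], [2, 4])
        right = self.make_set([1.1, 3.1, 5.1], [2.1, 4.1])
        pairs = sq.match_extrema(left, right, max_lag_s=1.0)
        assert np.allclose(pairs.right_times - pairs.left_times, 0.1)

    def test_antiphase_lags_half_period(self):
        period = 2.0
        left = self.make_set([0.5, 2.5, 4.5], [1.5, 3.5])
        right = self.make_set([1.5, 3.5, 5.5], [0.5, 2.5, 4.5])
        pairs = sq.match_extrema(left, right, max_lag_s=period / 2)
        assert np.allclose(np.abs(pairs.left_times - pairs.right_times), period / 2)

    def test_no_pairs_in_window_raises(self):
        with pytest.raises(sq.MatchingError):
            sq.match_extrema(
                self.make_set([0.0], []), self.make_set([5.0], []), max_lag_s=1.0
            )


class TestEstimateOffsetScale:
    def draws_from(self, func, grid, n=4):
        return np.tile(func(grid), (n, 1))

    def test_identical_draws_unity(self):
        grid = np.linspace(0, 8, 1500)
        draws = self.draws_from(lambda t: 6 * np.sin(2 * np.pi * t / 2.0), grid)
        est = sq.estimate_offset_scale(draws, draws.copy(), grid)
        assert est.amplitude_scale == pytest.approx(1.0, abs=1e-9)
        assert est.phase_offset_deg == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_scale_and_offset(self):
        """Left at half amplitude, lagging 0.1 s of a 2 s period = 18 deg."""
        grid = np.linspace(0, 8, 4000)
        left = self.draws_from(
            lambda t: 3 * np.sin(2 * np.pi * (t - 0.1) / 2.0) + 120, grid
        )
        right = self.draws_from(lambda t: 6 * np.sin(2 * np.pi * t / 2.0) + 140, grid)
        est = sq.estimate_offset_scale(left, right, grid, reference="right")
        assert est.amplitude_scale == pytest.approx(0.5, abs=1e-3)
        assert est.phase_offset_deg == pytest.approx(18.0, abs=0.2)
        assert est.time_delay_s == pytest.approx(0.1, abs=2e-3)

    def test_antiphase_reports_180(self):
        grid = np.linspace(0, 6, 3000)
        left = self.draws_from(lambda t: 5 * np.sin(2 * np.pi * t / 2.0 + np.pi), grid)
        right = self.draws_from(lambda t: 5 * np.sin(2 * np.pi * t / 2.0), grid)
        est = sq.estimate_offset_scale(left, right, grid, reference="right")
        assert abs(abs(est.phase_offset_deg) - 180.0) < 1.0

    def test_swapping_reference_inverts_scale_and_offset(self):
        rng = np.random.default_rng(11)
        grid = np.linspace(0, 8, 1600)
        base_l = 4 * np.sin(2 * np.pi * (grid - 0.08) / 1.9) + 115
        base_r = 10 * np.sin(2 * np.pi * grid / 1.9) + 140
        left = base_l + 0.05 * rng.standard_normal((60, len(grid)))
        right = base_r + 0.05 * rng.standard_normal((60, len(grid)))
        a = sq.estimate_offset_scale(left, right, grid, reference="right")
        b = sq.estimate_offset_scale(left, right, grid, reference="left")
        assert a.amplitude_scale * b.amplitude_scale == pytest.approx(1.0, abs=0.02)
        assert a.phase_offset_deg == pytest.approx(-b.phase_offset_deg, abs=1.5)

    def test_flat_draws_unstable(self):
        grid = np.linspace(0, 8, 800)
        flat = np.full((6, 800), 100.0)
        wavy = self.draws_from(lambda t: 5 * np.sin(2 * np.pi * t / 2.0), grid, n=6)
        with pytest.raises(sq.UnstableEstimateError):
            sq.estimate_offset_scale(flat, wavy, grid, period_s=2.0)


class TestPhaseToDelay:
    @pytest.mark.parametrize(
        "phase,period,expected,places",
        [
            (18.2, 1.93, 0.10, 2),   # quiet-breathing conversion
            (59.5, 0.33, 0.05, 2),   # sniff conversion
            (0.0, 1.7, 0.0, 9),
            (180.0, 2.0, 1.0, 9),
        ],
    )
    def test_printed_conversions(self, phase, period, expected, places):
        assert round(sq.phase_to_delay(phase, period), places) == expected

    def test_nonpositive_period_rejected(self):
        with pytest.raises(sq.InvalidParameterError):
            sq.phase_to_delay(10.0, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        phase=st.floats(-720, 720),
        period=st.floats(0.01, 100),
        c=st.floats(0.1, 10),
    )
    def test_linear_in_both_arguments(self, phase, period, c):
        d = sq.phase_to_delay(phase, period)
        assert sq.phase_to_delay(c * phase, period) == pytest.approx(c * d, rel=1e-9)
        assert sq.phase_to_delay(phase, c * period) == pytest.approx(c * d, rel=1e-9)
        assert sq.phase_to_delay(360.0, period) == pytest.approx(period, rel=1e-12)
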
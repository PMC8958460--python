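# Methods

This note records the model, the estimation choices, and the design
decisions behind `sniffquant`, together with what the synthetic tests
do and do not demonstrate.

## Signal model and conventions

Each hemidiaphragm's dome elevation over a breathing or sniffing window
is treated as a noisy sinusoid: apex row
`r(t) = baseline − A sin(2πt/T + φ) + ε`. Coordinates are 0-based and
row-major with rows increasing caudally; elevation is reported as
`reference_row − apex_row` so ascent (cranial motion) is positive, and
paradoxical motion is exactly anti-phase (180°) in one shared sign
convention. ROIs are half-open rectangles. The between-side phase
offset is positive when the non-reference (clinically suspected) side
lags the reference side; the time delay is `offset/360 × T`, with `T`
the non-reference side's fitted period.

## Tracking

Canny edge detection (Gaussian σ = 2 px; hysteresis thresholds 0.1 and
0.2 of the maximum smoothed Sobel gradient magnitude, so the same
fractions work across exposure levels) delineates the lung/abdomen
boundary. The dome sample per frame is the minimum row of the largest
8-connected edge component inside the ROI; among tied rows the
lower-median column's pixel is taken. These replace the human expert's
per-frame pixel pick with a deterministic rule; a CSV of manual
overrides is honoured verbatim where supplied. Frames without a usable
edge become NaN gaps (never interpolated here); more than 25% gaps on a
side aborts tracking. On noiseless synthetic renders the tracker stays
within 1.5 px of ground truth; residual error is dominated by edge
rasterisation, which quantises the apex row.

## Gaussian-process smoothing

Squared-exponential kernel plus white noise. Hyperparameters maximise
the log marginal likelihood via bounded L-BFGS in log space with 5
restarts by default (delegated to scikit-learn's
`GaussianProcessRegressor`); bounds are σ_f ∈ [0.1, 100] px,
ℓ ∈ [2/frame_rate, duration] s, σ_n ∈ [0.05, 20] px. A jitter of
1e-8·σ_f² on the training diagonal stabilises the Cholesky
factorisation; posterior draws escalate diagonal jitter from 1e-10·σ_f²
to 1e-4·σ_f² before failing.

Two posterior spreads are exposed: the **latent** function sd (used for
the 95% band, mean ± 1.96 sd, pointwise) and the noise-inclusive
**predictive** sd, which tends to √(σ_f² + σ_n²) far from data. The
band describes the smoothed motion itself, so it uses the latent sd —
this is what makes the empirical coverage of the true noiseless curve
land near 95% in simulation. Prediction grids are capped to the data
span padded by one length scale (beyond that the posterior reverts to
the prior and estimates would be artefacts); the default grid places 10
points per frame interval so the fast sniff waveform (~0.3 s period at
30 frames/s) is resolved.

## Waveform estimation

Single-sinusoid least squares with frequency initialised from the
dominant FFT peak (Lomb–Scargle when sampling is non-uniform; a peak
below 8× the median non-DC power is declared degenerate). Amplitude is
reported non-negative with the sign absorbed into phase.

Peaks/troughs of the smoothed mean use a prominence threshold of 0.5 px
(below plausible dome motion, above post-smoothing wiggle); consecutive
same-type extrema are reduced to the more extreme one so peaks and
troughs alternate. Matching across sides is greedy nearest-in-time,
one-to-one, same-type, within half a period, ties toward the earlier
extremum.

The phase offset is the least-squares time shift over matched pairs —
computed **on the circle** (pair lags are mapped to angles and averaged
as vectors) so that exact anti-phase, where individual pairs sit at
±T/2, does not cancel to zero. The amplitude scale is the least-squares
ratio of extremum excursions about each side's own mean, which makes it
invariant to the baseline elevation difference between the domes.
Matching peaks/troughs (rather than differencing fitted sinusoid
phases) is the primary estimator because it stays meaningful when the
two sides' periods differ slightly; the sinusoid-phase difference is
kept as a cross-check diagnostic in the report.

Uncertainty: every quantity is recomputed on each of 500 (default)
joint GP posterior draws per side and reported as mean ± SD across
draws. Published "±" values of this kind are not otherwise defined;
this package pins them as Monte-Carlo SDs over posterior draws.
Per-draw periods come from mean extremum spacing and per-draw
amplitude/phase from the linear solve at that period — within a few
percent of full nonlinear refits at a small fraction of the cost.

## Statistics and classification

`compare_params` is a Welch two-sample t-test on summary statistics
(mean, SD, n per side) with Welch–Satterthwaite degrees of freedom.
For the side-to-side amplitude and frequency tests the pipeline passes
**n = number of observed breath cycles**, not the number of draws:
draws are samples of a single record, so information about between-side
differences accrues per breath, while using n = draws would declare any
microscopic difference significant. Frequency is compared on 1/T.

The paradox test is a one-sample z-test of the wrapped phase offset
(circular distance) against 180°, using the draw-based SD. Paradox is
supported only when 180° is **not** rejected and 0° **is** rejected —
a necessary-and-guarded reading that prevents a huge-uncertainty
estimate from being labelled paradoxical.

Classification rule, in order: paradox supported →
`paradoxical_paralysis_suggestive`; significant amplitude asymmetry
with the affected side below 75% of the contralateral →
`weakness_suggestive`; motion present otherwise →
`within_normal_limits`; unusable estimates or no prominent motion →
`indeterminate`. The 75% practical-significance margin encodes the
clinical observation that mild asymmetry is common in healthy
individuals; without it, sub-pixel systematic tracking differences
(which the posterior SD cannot represent) would flag symmetric motion
as weakness. The rule is symmetric in the scale (min(s, 1/s)), so
swapping the left/right labels never changes the verdict.

## Synthetic scenes

The generator renders two downward-opening parabolic intensity
boundaries (dark lung above, brighter abdomen below, 1-px linear ramp
at the boundary for sub-pixel apex information) whose apices follow
configurable sinusoids, plus seeded Gaussian apex jitter (0.3 px) and
pixel noise (0.02 intensity units). Canonical scenarios: quiet
breathing at ~1.9 s period for 8 s, sniffing at ~0.3 s for 3 s, 30
frames/s, 256×256 px; `normal` has equal amplitudes and a 10° lag,
`weakness` an asymmetric 9.3 vs 23.7 px pair lagging 18.2°, `paralysis`
an exact 180° offset. Amplitudes of a few to a few tens of pixels
correspond to the 1–2.5 cm excursions seen clinically at typical
fluoroscopic geometry.

What the scenes deliberately omit: ribs, cardiac shadow and bowel gas
(confounders for edge detection), scatter and dose physics, breath-to-
breath variability of period and amplitude, and projection effects of
the 3-D dome. Passing tests therefore demonstrate correctness of the
measurement chain under the stated signal model, not robustness to
every clinical artefact; on real data the manual-override path exists
precisely because automatic tracking can lock onto the wrong edge.

## Problem sizes and numerical choices

Simulation studies in the test suite and the acceptance script use
12 s × 30 Hz trajectory records (parameter recovery; 50 replicates),
6 s records for band-coverage calibration (200 replicates), 200-draw /
5×-oversampled pipelines for the classification sweep (10 seeds ×
3 scenarios) and 60-draw analyses for recovery replicates — sizes
chosen so each study gives stable statistics on a single CPU. Degenerate
inputs are handled explicitly: constant frames yield empty edge maps,
constant series raise degenerate-signal errors, empty extrema sets flag
"no motion", and matching failure in more than half the draws raises an
unstable-estimate error rather than reporting a spurious offset.

## Known limitations

* A single stationary sinusoid per window: no chirps, no breath-by-
  breath segmentation, no harmonic decomposition.
* One GP per side: the two sides are smoothed independently rather
  than jointly (no cross-covariance model).
* The amplitude scale is defined on extremum excursions; with very few
  matched extrema (short windows) its draw-SD underestimates the true
  uncertainty.
* The effective sample size for the Welch tests (breath cycles) is a
  pragmatic choice; a mixed model over segmented breaths would be the
  principled generalisation and is out of scope.
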
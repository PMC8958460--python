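"""Side-to-side significance tests and motion classification.

Amplitude and frequency differences between the hemidiaphragms are
tested with a Welch-style two-sample t-test applied to Monte-Carlo
summaries (mean, SD, n) of the posterior-draw parameter distributions.
The paradox criterion — a 180-degree phase difference between the two
elevation signals — is tested on the wrapped phase offset using its
draw-based SD; paradoxical motion is supported only when 180 degrees is
*not* rejected while 0 degrees *is*, so a wildly uncertain offset is
never labelled paradoxical.

The final label is a deterministic rule over those test outcomes:
paradox supported -> paralysis-suggestive; otherwise a significant
amplitude asymmetry -> weakness-suggestive; otherwise motion with no
significant asymmetry -> within normal limits; unusable estimates ->
indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as st

from .errors import InvalidParameterError
from .waveform import PhaseScaleEstimate, circular_distance_deg

__all__ = [
    "TestResult",
    "ParadoxTestResult",
    "MotionClassification",
    "compare_params",
    "test_paradoxical",
    "classify",
    "LABELS",
]

ALPHA = 0.05

#: Physiologic mild-asymmetry allowance: healthy hemidiaphragms commonly
#: move with mildly unequal excursions, so an amplitude reduction only
#: suggests weakness when the affected side falls below this fraction of
#: the contralateral side (in addition to statistical significance).
MILD_ASYMMETRY_SCALE = 0.75

LABELS = (
    "paradoxical_paralysis_suggestive",
    "weakness_suggestive",
    "within_normal_limits",
    "indeterminate",
)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test at the 95% level."""

    statistic: float
    p_value: float
    significant_at_95: bool
    estimate: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError("p_value must lie in [0, 1]")
        if self.ci95[0] > self.ci95[1]:
            raise InvalidParameterError("ci95 low must be <= high")
        if self.significant_at_95 != (self.p_value < ALPHA):
            raise InvalidParameterError("significant_at_95 must equal p < 0.05")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant_at_95": self.significant_at_95,
            "estimate": self.estimate,
            "ci95": list(self.ci95),
        }


@dataclass(frozen=True)
class ParadoxTestResult(TestResult):
    """Paradox test: TestResult fields describe H0: offset = 180 deg.

    ``p_value_zero`` is the companion test of H0: offset = 0 deg;
    ``paradox_supported`` requires 180 not rejected AND 0 rejected.
    """

    p_value_zero: float = 1.0
    paradox_supported: bool = False

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["p_value_zero"] = self.p_value_zero
        d["paradox_supported"] = self.paradox_supported
        return d


def compare_params(
    est_a: float,
    sd_a: float,
    est_b: float,
    sd_b: float,
    n_a: int,
    n_b: int,
) -> TestResult:
    """Welch two-sample t-test from summary statistics.

    Treats the two (mean, SD, n) summaries as independent samples and
    uses Welch-Satterthwaite degrees of freedom with a two-sided p.
    Degenerate zero-SD inputs fall back to the exact-equality
    convention: p = 1 when the estimates agree, p = 0 otherwise.
    """
    if n_a < 2 or n_b < 2:
        raise InvalidParameterError("need n >= 2 per side")
    if sd_a < 0 or sd_b < 0:
        raise InvalidParameterError("SDs must be non-negative")
    diff = est_a - est_b
    var = sd_a**2 / n_a + sd_b**2 / n_b
    if var == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        stat = 0.0 if diff == 0.0 else np.inf * np.sign(diff)
        return TestResult(
            statistic=float(stat),
            p_value=p,
            significant_at_95=p < ALPHA,
            estimate=float(diff),
            ci95=(float(diff), float(diff)),
        )
    se = float(np.sqrt(var))
    tstat = diff / se
    df = var**2 / (
        (sd_a**2 / n_a) ** 2 / (n_a - 1) + (sd_b**2 / n_b) ** 2 / (n_b - 1)
    )
    p = float(2.0 * st.t.sf(abs(tstat), df))
    half = float(st.t.ppf(1.0 - ALPHA / 2.0, df) * se)
    return TestResult(
        statistic=float(tstat),
        p_value=p,
        significant_at_95=p < ALPHA,
        estimate=float(diff),
        ci95=(float(diff - half), float(diff + half)),
    )


def _phase_test(offset_deg: float, sd: float, h0_deg: float) -> tuple[float, float]:
    """z statistic and two-sided p for H0: offset = h0 (circular distance)."""
    dist = circular_distance_deg(offset_deg, h0_deg)
    if sd == 0.0:
        return (0.0, 1.0) if dist == 0.0 else (np.inf, 0.0)
    z = dist / sd
    return float(z), float(2.0 * st.norm.sf(z))


def test_paradoxical(est: PhaseScaleEstimate) -> ParadoxTestResult:
    """Test the estimated phase offset against the 180-degree paradox criterion.

    One-sample z-test on the wrapped phase offset using the draw-based
    SD and the circular distance min(|d|, 360-|d|).  With sd = 0 the
    decision degenerates to exact equality.
    """
    sd = est.phase_offset_sd
    if not np.isfinite(sd) or sd < 0:
        raise InvalidParameterError("estimate must carry a finite, non-negative sd")
    z180, p180 = _phase_test(est.phase_offset_deg, sd, 180.0)
    _, p0 = _phase_test(est.phase_offset_deg, sd, 0.0)
    d180 = circular_distance_deg(est.phase_offset_deg, 180.0)
    ci = (max(0.0, d180 - 1.96 * sd), min(180.0, d180 + 1.96 * sd))
    return ParadoxTestResult(
        statistic=z180,
        p_value=p180,
        significant_at_95=p180 < ALPHA,
        estimate=d180,
        ci95=ci,
        p_value_zero=p0,
        paradox_supported=(p180 >= ALPHA) and (p0 < ALPHA),
    )


@dataclass(frozen=True)
class MotionClassification:
    """Deterministic motion label with a human-readable rationale."""

    label: str
    rationale: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise InvalidParameterError(f"label must be one of {LABELS}")

    def to_dict(self) -> dict:
        return {"label": self.label, "rationale": self.rationale}


def classify(
    ampl_test: Optional[TestResult],
    scale: Optional[PhaseScaleEstimate],
    paradox: Optional[ParadoxTestResult],
    motion_present: bool,
) -> MotionClassification:
    """Apply the fixed classification rule.

    1. unusable inputs or no detectable motion -> indeterminate;
    2. paradox supported -> paradoxical_paralysis_suggestive;
    3. significant amplitude asymmetry beyond the physiologic
       mild-asymmetry band (affected side below
       ``MILD_ASYMMETRY_SCALE`` of the contralateral) ->
       weakness_suggestive, whichever side the scale was referenced to;
    4. otherwise -> within_normal_limits.
    """
    if ampl_test is None or scale is None or paradox is None:
        return MotionClassification(
            label="indeterminate",
            rationale="insufficient extrema or unstable estimates",
        )
    if not motion_present:
        return MotionClassification(
            label="indeterminate",
            rationale="no prominent dome motion detected on either side",
        )
    if paradox.paradox_supported:
        return MotionClassification(
            label="paradoxical_paralysis_suggestive",
            rationale=(
                f"phase offset {scale.phase_offset_deg:.1f} deg is consistent with "
                f"180 deg (p={paradox.p_value:.3g}) and inconsistent with 0 deg "
                f"(p={paradox.p_value_zero:.3g}): paradoxical motion"
            ),
        )
    s = scale.amplitude_scale
    reduction = min(s, 1.0 / s) if s > 0 else 0.0  # affected/contralateral
    if ampl_test.significant_at_95 and reduction < MILD_ASYMMETRY_SCALE:
        affected = scale.reference if s > 1.0 else (
            "left" if scale.reference == "right" else "right"
        )
        pct = 100.0 * reduction
        return MotionClassification(
            label="weakness_suggestive",
            rationale=(
                f"significant amplitude asymmetry (p={ampl_test.p_value:.3g}); "
                f"{affected} side moves at {pct:.1f}% of the contralateral side "
                f"without paradoxical motion"
            ),
        )
    return MotionClassification(
        label="within_normal_limits",
        rationale=(
            f"motion present with no significant amplitude asymmetry "
            f"(p={ampl_test.p_value:.3g}) and no paradoxical phase relation "
            f"(offset {scale.phase_offset_deg:.1f} deg)"
        ),
    )
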
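"""Synthetic cohort and waveform generation for pipeline testing.

No raw subject-level data accompanies the published cohorts, so this module
generates synthetic data at three levels, each calibrated to the published
group-level statistics:

1. **Ratio level** — asymmetry-ratio samples drawn from a skew-normal
   distribution moment-matched (mean, SD, skewness) to the published cohort
   moments, via closed-form inversion of the skew-normal moment equations.
   Where a published skewness exceeds the skew-normal feasibility bound
   (|skewness| < 0.9953), the generator falls back to a positively-truncated
   normal matched on mean and SD and records the compromise.
2. **Subject level** — bilateral jaw-jerk and MEP amplitudes drawn per
   subject from the published group means/SDs, from which ratios and
   classifications can be computed end to end.
3. **Waveform level** — biphasic evoked-response sweeps with controlled
   peak-to-peak amplitude, latency and additive noise, for exercising trial
   averaging and amplitude extraction.

All sampling is seeded; identical seeds give identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .classifier import SubjectRecord
from .waveform import EMGTrace, TrialSet

__all__ = [
    "RatioDistributionSpec",
    "AmplitudeSpec",
    "WaveformSpec",
    "SkewNormalParams",
    "SkewnessInfeasibleError",
    "MAX_SKEWNORM_SKEWNESS",
    "fit_skew_normal",
    "ratio_distribution",
    "sample_ratios",
    "sample_subjects",
    "synthesize_waveform",
    "TABLE1_RATIO_SPECS",
    "AMPLITUDE_SPECS",
]

#: supremum of |skewness| attainable by a skew-normal distribution
MAX_SKEWNORM_SKEWNESS = 0.5 * (4.0 - math.pi) * (2.0 / math.pi) ** 1.5 \
    / (1.0 - 2.0 / math.pi) ** 1.5  # ~0.99527

#: amplitudes are floored here (mV) when a draw comes out non-positive
AMPLITUDE_FLOOR_MV = 0.01


class SkewnessInfeasibleError(ValueError):
    """Target skewness outside the skew-normal family's attainable range."""


@dataclass(frozen=True)
class RatioDistributionSpec:
    """Target moments for one cohort's asymmetry-ratio distribution."""

    mean: float
    sd: float
    skewness: float
    group: str = ""
    measure: str = ""
    family: Literal["skew_normal", "truncated_normal"] = "skew_normal"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class SkewNormalParams:
    """Skew-normal parameters (shape ``alpha``, location ``xi``, scale
    ``omega``) in scipy's ``skewnorm(a, loc, scale)`` convention."""

    shape: float
    location: float
    scale: float

    def frozen(self) -> stats.rv_continuous:
        return stats.skewnorm(self.shape, loc=self.location, scale=self.scale)


# ---------------------------------------------------------------------------
# ratio-level generation
# ---------------------------------------------------------------------------

def fit_skew_normal(spec: RatioDistributionSpec) -> SkewNormalParams:
    """Invert the skew-normal moment equations for given mean/SD/skewness.

    With delta = alpha / sqrt(1 + alpha^2) the skew-normal has

        mean     = xi + omega * delta * sqrt(2/pi)
        variance = omega^2 * (1 - 2 delta^2 / pi)
        skewness = (4 - pi)/2 * (delta sqrt(2/pi))^3
                                 / (1 - 2 delta^2/pi)^(3/2)

    which inverts in closed form: the skewness equation fixes |delta|, the
    variance equation then fixes omega, and the mean equation fixes xi.
    Raises :class:`SkewnessInfeasibleError` for |skewness| >= 0.9953, where
    no skew-normal exists.
    """
    g1 = spec.skewness
    if abs(g1) >= MAX_SKEWNORM_SKEWNESS:
        raise SkewnessInfeasibleError(
            f"|skewness|={abs(g1):.3g} >= {MAX_SKEWNORM_SKEWNESS:.4f}; "
            "use the truncated_normal family instead"
        )
    if g1 == 0.0:
        return SkewNormalParams(shape=0.0, location=spec.mean, scale=spec.sd)
    c = (2.0 * abs(g1) / (4.0 - math.pi)) ** (2.0 / 3.0)
    delta = math.copysign(math.sqrt(math.pi / 2.0 * c / (1.0 + c)), g1)
    alpha = delta / math.sqrt(1.0 - delta ** 2)
    omega = spec.sd / math.sqrt(1.0 - 2.0 * delta ** 2 / math.pi)
    xi = spec.mean - omega * delta * math.sqrt(2.0 / math.pi)
    return SkewNormalParams(shape=alpha, location=xi, scale=omega)


def ratio_distribution(spec: RatioDistributionSpec):
    """Frozen scipy distribution for a ratio spec, with family fallback.

    Returns ``(frozen_dist, spec_used)``: a skew-normal when the target
    skewness is feasible and the spec requests it, otherwise a normal
    truncated at zero matched on the parent mean/SD (for the published
    specs the truncated mass is negligible, so the realized moments stay
    close to the targets; the returned spec records the family actually
    used so the compromise is visible).
    """
    if (spec.family == "skew_normal"
            and abs(spec.skewness) < MAX_SKEWNORM_SKEWNESS):
        return fit_skew_normal(spec).frozen(), spec
    a = (0.0 - spec.mean) / spec.sd
    dist = stats.truncnorm(a, np.inf, loc=spec.mean, scale=spec.sd)
    return dist, replace(spec, family="truncated_normal")


def sample_ratios(params, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` non-negative ratios from a fitted ratio distribution.

    ``params`` may be a :class:`SkewNormalParams`, a frozen scipy
    distribution, or a :class:`RatioDistributionSpec` (fitted on the fly
    with family fallback).  Negative draws are rejected and redrawn so the
    returned ratios are valid amplitudes quotients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(params, RatioDistributionSpec):
        dist, _ = ratio_distribution(params)
    elif isinstance(params, SkewNormalParams):
        dist = params.frozen()
    else:
        dist = params
    rng = np.random.default_rng(seed)
    out = np.asarray(dist.rvs(size=n, random_state=rng), dtype=float)
    bad = out < 0
    while bad.any():
        out[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
        bad = out < 0
    return out


#: published cohort ratio moments (mean, SD, skewness) per group and measure
TABLE1_RATIO_SPECS: dict[tuple[str, str], RatioDistributionSpec] = {
    ("TMD", "bR-MEPs%"): RatioDistributionSpec(
        0.91, 0.22, -1.7, group="TMD", measure="bR-MEPs%"),
    ("control", "bR-MEPs%"): RatioDistributionSpec(
        0.93, 0.12, 1.5, group="control", measure="bR-MEPs%"),
    ("TMD", "ipJJ%"): RatioDistributionSpec(
        0.24, 0.14, 0.79, group="TMD", measure="ipJJ%"),
    ("control", "ipJJ%"): RatioDistributionSpec(
        0.61, 0.2, 0.21, group="control", measure="ipJJ%"),
}


# ---------------------------------------------------------------------------
# subject-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeSpec:
    """Group-level bilateral amplitude means/SDs (mV).

    ``side_correlation`` is the within-subject correlation between the two
    sides' amplitudes of one test; ``jj_mep_correlation`` couples a
    subject's jaw-jerk and MEP levels.  Neither is constrained by the
    published group statistics, so both default to 0.
    """

    jj_ref_mean: float
    jj_ref_sd: float
    jj_contra_mean: float
    jj_contra_sd: float
    mep_ref_mean: float
    mep_ref_sd: float
    mep_contra_mean: float
    mep_contra_sd: float
    group: Literal["control", "TMD"] = "TMD"
    side_correlation: float = 0.0
    jj_mep_correlation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("jj_ref", "jj_contra", "mep_ref", "mep_contra"):
            if getattr(self, f"{name}_mean") < 0:
                raise ValueError(f"{name}_mean must be non-negative")
            if getattr(self, f"{name}_sd") <= 0:
                raise ValueError(f"{name}_sd must be positive")
        for rho in (self.side_correlation, self.jj_mep_correlation):
            if not -1 < rho < 1:
                raise ValueError("correlations must lie in (-1, 1)")


#: published group amplitude means/SDs: reference side is the pain side for
#: patients, the non-preferred masticatory side for controls
AMPLITUDE_SPECS: dict[str, AmplitudeSpec] = {
    "control": AmplitudeSpec(
        jj_ref_mean=0.8, jj_ref_sd=0.5, jj_contra_mean=1.3, jj_contra_sd=0.6,
        mep_ref_mean=4.4, mep_ref_sd=1.9, mep_contra_mean=4.7,
        mep_contra_sd=2.1, group="control"),
    "TMD": AmplitudeSpec(
        jj_ref_mean=0.4, jj_ref_sd=0.4, jj_contra_mean=1.5, jj_contra_sd=1.1,
        mep_ref_mean=4.2, mep_ref_sd=2.9, mep_contra_mean=5.2,
        mep_contra_sd=2.5, group="TMD"),
}


def sample_subjects(spec: AmplitudeSpec, n: int, seed: int,
                    floor_mv: float = AMPLITUDE_FLOOR_MV,
                    ) -> list[SubjectRecord]:
    """Draw ``n`` subjects' bilateral JJ and MEP amplitudes.

    The four amplitudes are jointly Gaussian with the spec's means/SDs and
    correlation structure (side_correlation within a test,
    jj_mep_correlation between same-side JJ and MEP).  Non-positive draws
    are floored at ``floor_mv`` to keep amplitudes physical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    means = np.array([spec.jj_ref_mean, spec.jj_contra_mean,
                      spec.mep_ref_mean, spec.mep_contra_mean])
    sds = np.array([spec.jj_ref_sd, spec.jj_contra_sd,
                    spec.mep_ref_sd, spec.mep_contra_sd])
    rho_s, rho_jm = spec.side_correlation, spec.jj_mep_correlation
    corr = np.array([
        [1.0, rho_s, rho_jm, 0.0],
        [rho_s, 1.0, 0.0, rho_jm],
        [rho_jm, 0.0, 1.0, rho_s],
        [0.0, rho_jm, rho_s, 1.0],
    ])
    cov = corr * np.outer(sds, sds)
    draws = rng.multivariate_normal(means, cov, size=n)
    draws = np.maximum(draws, floor_mv)
    kind = "pain_side" if spec.group == "TMD" else "non_preferred_side"
    return [
        SubjectRecord(
            subject_id=f"{spec.group}_{i:04d}",
            jj_ip_ref=float(row[0]), jj_ip_contra=float(row[1]),
            mep_ref=float(row[2]), mep_contra=float(row[3]),
            group=spec.group, reference_side="right",
            reference_side_kind=kind,
        )
        for i, row in enumerate(draws)
    ]


# ---------------------------------------------------------------------------
# waveform-level generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformSpec:
    """Parameters of a synthetic biphasic evoked response.

    The clean trace is a positive Gaussian lobe at ``latency_ms`` followed
    by a negative lobe, rescaled so its peak-to-peak amplitude is exactly
    ``peak_to_peak_mv``; independent Gaussian noise of ``noise_sd_mv`` is
    added per trial.
    """

    peak_to_peak_mv: float
    latency_ms: float = 10.0
    lobe_width_ms: float = 2.0
    lobe_separation_ms: float = 5.0
    negative_fraction: float = 0.4  # share of p2p carried by the trough
    noise_sd_mv: float = 0.0
    window_ms: float = 50.0
    sampling_rate: float = 20000.0
    side: Literal["left", "right"] = "right"
    test_type: Literal["JJ", "MEP"] = "JJ"

    def __post_init__(self) -> None:
        if self.peak_to_peak_mv < 0 or self.noise_sd_mv < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 < self.negative_fraction < 1:
            raise ValueError("negative_fraction must lie in (0, 1)")
        if not (0 <= self.latency_ms
                and self.latency_ms + self.lobe_separation_ms
                <= self.window_ms):
            raise ValueError("response must fit inside the window")


def _clean_waveform(spec: WaveformSpec) -> np.ndarray:
    n = round(spec.window_ms / 1000.0 * spec.sampling_rate)
    t = np.arange(n) / spec.sampling_rate * 1000.0
    pos = (1.0 - spec.negative_fraction) * np.exp(
        -0.5 * ((t - spec.latency_ms) / spec.lobe_width_ms) ** 2)
    neg = spec.negative_fraction * np.exp(
        -0.5 * ((t - spec.latency_ms - spec.lobe_separation_ms)
                / spec.lobe_width_ms) ** 2)
    w = pos - neg
    span = w.max() - w.min()
    if span > 0 and spec.peak_to_peak_mv > 0:
        w *= spec.peak_to_peak_mv / span
    elif spec.peak_to_peak_mv == 0:
        w = np.zeros_like(w)
    return w


def synthesize_waveform(spec: WaveformSpec, seed: int,
                        n_trials: int = 10) -> TrialSet:
    """Generate ``n_trials`` noisy sweeps sharing one clean biphasic shape.

    With ``noise_sd_mv = 0`` the averaged trace's peak-to-peak amplitude
    equals ``peak_to_peak_mv`` exactly; with noise it converges to it at
    the usual 1/sqrt(n_trials) rate.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    clean = _clean_waveform(spec)
    trials = []
    for _ in range(n_trials):
        noise = rng.normal(0.0, spec.noise_sd_mv, size=clean.size) \
            if spec.noise_sd_mv > 0 else 0.0
        trials.append(EMGTrace(
            samples=clean + noise,
            sampling_rate=spec.sampling_rate,
            window_ms=spec.window_ms,
            side=spec.side,
            test_type=spec.test_type,
        ))
    return TrialSet(trials)
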
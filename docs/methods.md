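# Methods

## The screening problem

Pain from temporomandibular disorders (TMD) presents much like other
orofacial pain (OP), and both can mask early organic neurological disease
involving the trigeminal system. Two bedside electrophysiological tests
probe different levels of that system on both sides at once:

* the **trigeminal-root motor evoked potential** (bR-MEP), elicited by
  bilateral electrical transcranial stimulation and recorded from the
  masseter muscles, probes the *organic* integrity of the trigeminal motor
  fibers;
* the **jaw-jerk reflex** (JJ), a monosynaptic stretch reflex elicited by a
  chin tap while the mandible is held in the intercuspal position, probes
  the *functional* facilitation of the reflex arc, which fails on the
  painful side in TMD.

For each test the analysis quantity is the bilateral asymmetry ratio

    r = A_reference / A_contralateral

where `A` is the peak-to-peak amplitude (mV) of the averaged evoked trace
and the *reference* side is the painful side in patients (the non-preferred
masticatory side in controls). The reference side is always the numerator;
the ratio is deliberately not folded to min/max, so r > 1 is meaningful.
A ratio r maps onto a "between-side skewness" percentage (1 − r) × 100.

## The two-step classifier

Screening thresholds are low percentiles of a pain-free control cohort's
ratio distributions:

* **cutoff a** = control 5th percentile of the MEP ratio (published 0.76);
* **cutoff b** = control 5th percentile of the intercuspal JJ ratio
  (published 0.32).

Classification is a short-circuit cascade:

1. MEP ratio < cutoff a → **ORGANIC_DAMAGE**, exit (no step 2);
2. otherwise, JJ ratio < cutoff b → **TMD**, else → **OP**.

Equality at a cutoff passes the screen at both steps. The published
narrative fixes ≥ as pass at step 1; at step 2 the source notation is
contradictory about exact equality, and we assign it to OP for consistency
with step 1 — a measure exactly at the control 5th percentile is not
evidence of abnormality. This convention is asserted explicitly in the test
suite and documented here because a ratio landing exactly on a cutoff,
while measure-zero in theory, happens with rounded clinical inputs.

Degenerate inputs: an absent (zero) contralateral MEP response is maximal
asymmetry and fails step 1 with an `absent_response` flag; an absent
contralateral JJ after a step-1 pass leaves step 2 undefined and raises an
error rather than guessing. The model has no "healthy" label — it is
defined only for subjects presenting with pain.

## Amplitude extraction

Evoked sweeps are averaged pointwise over trials *first* (20 trials in the
reference acquisition protocol, 10 in the worked clinical cases) and the
peak-to-peak amplitude max − min is then measured on the averaged trace,
optionally within a post-stimulus sub-window. We do not average per-trial
peak-to-peaks: per-trial noise extrema bias that estimator upward, while
averaging first cancels noise at the usual 1/√n rate.

The facilitation context of the intercuspal JJ is checked against a
maximal-voluntary-contraction (MVC) estimate: MVC is the mean over clench
trials of the mean rectified EMG amplitude (rectified mean rather than RMS;
the acquisition protocol specifies only a "mean EMG value", so this is a
documented, configurable choice), and the background EMG of a trial is
compared with the 20% MVC target within a relative tolerance band
(default ±25%).

Hardware band-pass settings (20–2000 Hz for JJ, 0.1–2000 Hz for MEP) are
carried as metadata only; traces are assumed already conditioned and no
digital filtering is applied. Amplitudes are mV throughout; µV inputs are
converted on load.

## Cohort statistics and cutoff derivation

Descriptive summaries use the n−1 sample variance, the adjusted
Fisher-Pearson skewness, and **excess** kurtosis — the published control
kurtosis of −1.1 is impossible under the raw (Pearson) convention, which
fixes the interpretation. Percentiles interpolate linearly between closest
ranks by default; the raw lower-order-statistic convention is exposed
(`method="lower"`) because with a control cohort of n ≈ 36 the two differ
materially at the 5th percentile and the original derivation's convention
is unstated.

The intergroup comparison is a two-sided Mann-Whitney U test: the exact
null distribution when the combined sample size is ≤ 20 and there are no
ties, the tie-corrected normal approximation otherwise (delegated to
`scipy.stats.mannwhitneyu`; the test suite checks the exact path against an
independent exhaustive-enumeration oracle for all sample shapes up to
6 × 6).

The published cutoff pair (0.76, 0.32) ships as a frozen default because
the reference cohort's raw data was never deposited; deriving new cutoffs
from a user cohort is an explicit opt-in, with an optional percentile
bootstrap CI as an extension beyond the original plain-percentile
procedure.

## Synthetic data generator

No subject-level data is public, so the generator emulates the *published
group-level statistics* at three levels. Its defaults are the study
conditions, not tuning knobs.

**Ratio level.** Ratios are drawn from a skew-normal distribution whose
location/scale/shape are obtained by closed-form inversion of the
skew-normal moment equations at the published (mean, SD, skewness) of each
group × measure cell: TMD ipJJ% (0.24, 0.14, 0.79), control ipJJ%
(0.61, 0.20, 0.21), control bR-MEPs% (0.93, 0.12, 1.5), TMD bR-MEPs%
(0.91, 0.22, −1.7). The skew-normal family caps |skewness| at ≈ 0.9953, so
the two MEP rows are infeasible; for those the generator falls back to a
normal truncated at zero with the published mean/SD as parent parameters
(the truncated mass is < 10⁻⁴ there, so realized moments stay at the
targets) and records the family actually used. Kurtosis is not matched —
three-moment matching only. The skew-normal choice is independently
corroborated: the fitted TMD ipJJ% distribution puts 74.4% of its mass
below cutoff b, matching the reported ~75% of the patient sample without
any fitting to that number. Negative ratio draws are rejected and redrawn.

**Subject level.** Bilateral JJ and MEP amplitudes are drawn jointly
Gaussian at the published group means/SDs (e.g. TMD: JJ 0.4 ± 0.4 mV pain
side, 1.5 ± 1.1 mV contralateral; MEP 4.2 ± 2.9 / 5.2 ± 2.5 mV).
Within-subject side-side and JJ-MEP correlations are unconstrained by the
published statistics and default to 0. Non-positive draws are floored at
0.01 mV, which biases small-mean cells slightly upward (the pain-side JJ
mean rises from 0.40 to ≈ 0.43); tolerances in tests account for this.

**Waveform level.** Synthetic sweeps are a two-lobe Gaussian biphasic shape
(positive lobe at the response latency, negative lobe a fixed separation
later, 60/40 amplitude split) rescaled to an exact target peak-to-peak
amplitude, plus white Gaussian noise per trial. This emulates only what the
amplitude pipeline consumes — a dominant positive and negative peak inside
the acquisition window. It does not emulate real EMG spectra, stimulus
artifacts, latency jitter, or trial-to-trial amplitude variability, so
passing round-trip tests demonstrate correctness of the averaging/
extraction/ratio/classification chain, not robustness to real-world
recording pathologies.

All sampling is seeded (`numpy.random.default_rng`); identical seeds give
identical cohorts.

## What the generator's calibration can and cannot show

Because the synthetic cohorts are moment-matched to published summaries
rather than resampled from raw data, cohort-level reproductions (cutoffs
near 0.76/0.32 from a large synthetic control cohort, ~75% of synthetic
patients below cutoff b, Mann-Whitney separation on the JJ ratio but not
the MEP ratio at n = 33/36) validate internal consistency of the published
numbers under a plausible distributional family — not the original data.
The published percentile tables and the reported patient-vs-control
p ≈ 10⁻¹² cannot be reproduced exactly without the raw cohort and are
covered by property-based tests instead.

## Problem sizes and numerical choices

Monte-Carlo checks use n = 10⁴ draws for percentile/fraction anchors
(sampling error ≈ 0.4 percentage points on the 75% fraction) and n = 10⁵
for moment-recovery checks; the end-to-end waveform round trip runs 100
seeded scenarios with intended ratios kept a 0.08 margin away from the
cutoffs so that residual noise after 10-trial averaging (sd 0.05 mV per
sample) cannot flip a label. Peak-to-peak on a sampled sinusoid is within
one sample period of the continuous extremum; tests use the corresponding
tolerance. Constant samples have undefined standardized moments and report
NaN skewness/kurtosis rather than raising.
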
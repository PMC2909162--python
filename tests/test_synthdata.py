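"""Synthetic cohorts: moment matching, determinism, waveform round-trips."""

import numpy as np
import pytest
from scipy import stats

from trigdx.cohort_stats import mann_whitney
from trigdx.synthdata import (AMPLITUDE_SPECS, MAX_SKEWNORM_SKEWNESS,
                              TABLE1_RATIO_SPECS, RatioDistributionSpec,
                              SkewnessInfeasibleError, WaveformSpec,
                              fit_skew_normal, ratio_distribution,
                              sample_ratios, sample_subjects,
                              synthesize_waveform)
from trigdx.waveform import average_trials, peak_to_peak
from trigdx.asymmetry import BilateralAmplitudes, side_ratio


class TestFitSkewNormal:
    def test_zero_skewness_reduces_to_normal(self):
        p = fit_skew_normal(RatioDistributionSpec(0.5, 0.1, 0.0))
        assert p.shape == 0.0
        assert p.location == 0.5 and p.scale == 0.1

    @pytest.mark.parametrize("mean, sd, skew", [
        (0.24, 0.14, 0.79),   # patient jaw-jerk ratio moments
        (0.61, 0.20, 0.21),   # control jaw-jerk ratio moments
        (0.5, 0.2, -0.6),
    ])
    def test_analytic_moments_round_trip(self, mean, sd, skew):
        p = fit_skew_normal(RatioDistributionSpec(mean, sd, skew))
        dist = p.frozen()
        m, v, g1 = dist.stats(moments="mvs")
        assert float(m) == pytest.approx(mean, abs=1e-9)
        assert float(np.sqrt(v)) == pytest.approx(sd, abs=1e-9)
        assert float(g1) == pytest.approx(skew, abs=1e-9)

    def test_infeasible_skewness_raises(self):
        with pytest.raises(SkewnessInfeasibleError):
            fit_skew_normal(RatioDistributionSpec(0.91, 0.22, -1.7))
        assert MAX_SKEWNORM_SKEWNESS == pytest.approx(0.9953, abs=1e-4)

    def test_family_fallback_for_infeasible_specs(self):
        spec = TABLE1_RATIO_SPECS[("TMD", "bR-MEPs%")]  # skewness -1.7
        dist, used = ratio_distribution(spec)
        assert used.family == "truncated_normal"
        assert float(dist.mean()) == pytest.approx(spec.mean, abs=0.02)

    def test_monte_carlo_confirms_inversion(self):
        spec = TABLE1_RATIO_SPECS[("TMD", "ipJJ%")]
        x = sample_ratios(fit_skew_normal(spec), 200_000, seed=5)
        assert x.mean() == pytest.approx(spec.mean, abs=0.005)
        assert x.std(ddof=1) == pytest.approx(spec.sd, abs=0.005)
        assert stats.skew(x) == pytest.approx(spec.skewness, abs=0.05)


class TestSampleRatios:
    def test_seeded_determinism(self):
        spec = TABLE1_RATIO_SPECS[("control", "ipJJ%")]
        a = sample_ratios(spec, 50, seed=9)
        b = sample_ratios(spec, 50, seed=9)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, sample_ratios(spec, 50, seed=10))

    def test_all_draws_non_negative(self):
        spec = RatioDistributionSpec(0.05, 0.2, 0.5)  # heavy negative mass
        x = sample_ratios(spec, 5000, seed=2)
        assert (x >= 0).all()

    def test_moment_recovery_at_large_n(self):
        spec = TABLE1_RATIO_SPECS[("TMD", "ipJJ%")]
        x = sample_ratios(spec, 100_000, seed=3)
        assert x.mean() == pytest.approx(0.24, abs=0.01)
        assert x.std(ddof=1) == pytest.approx(0.14, abs=0.01)

    def test_intergroup_separation_on_jj_not_mep(self):
        """Cohorts at the published group moments separate on the jaw-jerk
        ratio but not on the MEP ratio, at the published cohort sizes."""
        n_tmd, n_ctrl = 33, 36
        jj_t = sample_ratios(TABLE1_RATIO_SPECS[("TMD", "ipJJ%")],
                             n_tmd, seed=21)
        jj_c = sample_ratios(TABLE1_RATIO_SPECS[("control", "ipJJ%")],
                             n_ctrl, seed=22)
        mep_t = sample_ratios(TABLE1_RATIO_SPECS[("TMD", "bR-MEPs%")],
                              n_tmd, seed=23)
        mep_c = sample_ratios(TABLE1_RATIO_SPECS[("control", "bR-MEPs%")],
                              n_ctrl, seed=24)
        assert mann_whitney(jj_t, jj_c).p_value < 1e-6
        assert mann_whitney(mep_t, mep_c).p_value > 0.01


class TestSampleSubjects:
    def test_seeded_determinism(self):
        a = sample_subjects(AMPLITUDE_SPECS["TMD"], 10, seed=4)
        b = sample_subjects(AMPLITUDE_SPECS["TMD"], 10, seed=4)
        assert a == b

    def test_degenerate_sd_limit(self):
        from dataclasses import replace
        spec = replace(AMPLITUDE_SPECS["TMD"], jj_ref_sd=1e-9,
                       jj_contra_sd=1e-9, mep_ref_sd=1e-9,
                       mep_contra_sd=1e-9)
        recs = sample_subjects(spec, 5, seed=0)
        for r in recs:
            assert r.jj_ip_ref == pytest.approx(0.4, abs=1e-6)
            ratio = side_ratio(BilateralAmplitudes(r.mep_ref,
                                                   r.mep_contra)).value
            assert ratio == pytest.approx(4.2 / 5.2, abs=1e-6)

    def test_group_mean_jj_mep_fraction(self):
        """Pain-side group means reproduce the ~9.5% jaw-jerk-to-MEP
        facilitation fraction (floor truncation biases it slightly up)."""
        recs = sample_subjects(AMPLITUDE_SPECS["TMD"], 10_000, seed=6)
        jj = np.mean([r.jj_ip_ref for r in recs])
        mep = np.mean([r.mep_ref for r in recs])
        assert jj / mep == pytest.approx(0.095, abs=0.02)

    def test_metadata_by_group(self):
        ctrl = sample_subjects(AMPLITUDE_SPECS["control"], 2, seed=0)
        assert ctrl[0].reference_side_kind == "non_preferred_side"
        tmd = sample_subjects(AMPLITUDE_SPECS["TMD"], 2, seed=0)
        assert tmd[0].reference_side_kind == "pain_side"


class TestSynthesizeWaveform:
    def test_noiseless_amplitude_exact(self):
        spec = WaveformSpec(peak_to_peak_mv=3.0, noise_sd_mv=0.0)
        trials = synthesize_waveform(spec, seed=1, n_trials=5)
        avg = average_trials(trials)
        assert peak_to_peak(avg) == pytest.approx(3.0, abs=1e-12)

    def test_averaging_shrinks_amplitude_error(self):
        spec = WaveformSpec(peak_to_peak_mv=2.0, noise_sd_mv=0.4)
        single_err, avg_err = [], []
        for seed in range(30):
            trials = synthesize_waveform(spec, seed=seed, n_trials=20)
            single_err.append(abs(peak_to_peak(trials.trials[0]) - 2.0))
            avg_err.append(abs(peak_to_peak(average_trials(trials)) - 2.0))
        assert np.mean(avg_err) < np.mean(single_err) / 2

    def test_response_must_fit_window(self):
        with pytest.raises(ValueError):
            WaveformSpec(peak_to_peak_mv=1.0, latency_ms=48.0,
                         window_ms=50.0)

    def test_roundtrip_waveform_to_ratio(self):
        """Synthesize both sides at a known amplitude ratio, extract
        amplitudes, and recover the ratio."""
        ref = synthesize_waveform(
            WaveformSpec(peak_to_peak_mv=1.0, noise_sd_mv=0.01), seed=7)
        contra = synthesize_waveform(
            WaveformSpec(peak_to_peak_mv=2.5, noise_sd_mv=0.01, side="left"),
            seed=8)
        ratio = side_ratio(BilateralAmplitudes(
            peak_to_peak(average_trials(ref)),
            peak_to_peak(average_trials(contra)))).value
        assert ratio == pytest.approx(0.4, abs=0.02)
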
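"""Trial averaging, peak-to-peak extraction, MVC and facilitation checks."""

import numpy as np
import pytest

from trigdx.waveform import (DimensionalMismatchError, EMGTrace, TrialSet,
                             average_trials, check_facilitation,
                             estimate_mvc, peak_to_peak, read_trace_csv,
                             write_trace_csv)

FS = 20000.0


def make_trace(samples, side="right", test_type="JJ"):
    samples = np.asarray(samples, dtype=float)
    return EMGTrace(samples=samples, sampling_rate=FS,
                    window_ms=samples.size / FS * 1000.0,
                    side=side, test_type=test_type)


class TestEMGTrace:
    def test_window_consistency_enforced(self):
        with pytest.raises(ValueError, match="window_ms"):
            EMGTrace(samples=np.zeros(100), sampling_rate=FS, window_ms=50.0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            EMGTrace(samples=np.array([]), sampling_rate=FS, window_ms=0.0)

    def test_trialset_rejects_mixed_metadata(self):
        a = make_trace(np.zeros(100), side="right")
        b = make_trace(np.zeros(100), side="left")
        with pytest.raises(DimensionalMismatchError):
            TrialSet([a, b])


class TestAverageTrials:
    def test_identical_trials_unchanged(self):
        t = make_trace(np.sin(np.linspace(0, 6, 200)))
        avg = average_trials([t] * 20)
        np.testing.assert_allclose(avg.samples, t.samples, rtol=1e-12)
        assert avg.n_trials == 20

    def test_opposite_constants_cancel(self):
        plus = make_trace(np.full(100, 1.0))
        minus = make_trace(np.full(100, -1.0))
        avg = average_trials([plus, minus, plus, minus])
        np.testing.assert_array_equal(avg.samples, np.zeros(100))

    def test_matches_per_sample_mean_oracle_and_shrinks_noise(self, rng):
        """Averaging n noisy sinusoids equals the per-sample mean and
        leaves residual noise of sd ~ sigma/sqrt(n)."""
        clean = np.sin(2 * np.pi * np.linspace(0, 4, 1000))
        sigma, n = 0.5, 10
        trials = [make_trace(clean + rng.normal(0, sigma, clean.size))
                  for _ in range(n)]
        avg = average_trials(trials)
        oracle = np.mean([t.samples for t in trials], axis=0)
        np.testing.assert_allclose(avg.samples, oracle)
        resid_sd = (avg.samples - clean).std()
        assert resid_sd == pytest.approx(sigma / np.sqrt(n), rel=0.25)


class TestPeakToPeak:
    def test_flat_trace_is_zero(self):
        assert peak_to_peak(make_trace(np.full(100, 3.7))) == 0.0

    def test_sinusoid_gives_twice_amplitude(self):
        a = 1.3
        t = np.arange(1000) / FS
        trace = make_trace(a * np.sin(2 * np.pi * 200 * t))
        # within one sample of the true extremum
        assert peak_to_peak(trace) == pytest.approx(2 * a, rel=1e-3)

    def test_biphasic_wavelet_matches_bruteforce(self):
        t = np.arange(1000) / FS * 1000.0
        wave = (2.0 * np.exp(-0.5 * ((t - 10) / 1.5) ** 2)
                - 1.0 * np.exp(-0.5 * ((t - 20) / 1.5) ** 2))
        trace = make_trace(wave)
        brute = max(wave) - min(wave)
        assert peak_to_peak(trace) == pytest.approx(brute)
        assert peak_to_peak(trace) == pytest.approx(3.0, rel=1e-6)

    def test_search_window_restricts(self):
        t = np.arange(1000) / FS * 1000.0
        wave = np.where(t < 25, 0.0, 5.0) + np.where(t < 5, -2.0, 0.0)
        trace = make_trace(wave)
        assert peak_to_peak(trace) == pytest.approx(7.0)
        assert peak_to_peak(trace, (10.0, 24.0)) == pytest.approx(0.0)

    def test_window_outside_trace_errors(self):
        trace = make_trace(np.zeros(100))
        with pytest.raises(ValueError):
            peak_to_peak(trace, (0.0, 100.0))
        with pytest.raises(ValueError):
            peak_to_peak(trace, (3.0, 3.0))

    def test_translation_invariance_and_gain_linearity(self, rng):
        x = rng.normal(size=500)
        base = peak_to_peak(make_trace(x))
        assert peak_to_peak(make_trace(x + 11.0)) == pytest.approx(base)
        assert peak_to_peak(make_trace(3.5 * x)) == pytest.approx(3.5 * base)

    def test_average_amplitude_bounded_by_max_trial(self, rng):
        trials = [make_trace(rng.normal(size=300)) for _ in range(8)]
        avg_amp = peak_to_peak(average_trials(trials))
        assert avg_amp <= max(peak_to_peak(t) for t in trials) + 1e-12


class TestMVC:
    def test_constant_clenches(self):
        trials = [make_trace(np.full(100, 1.0), test_type="clench")] * 5
        est = estimate_mvc(trials)
        assert est.mvc_level == pytest.approx(1.0)
        assert est.n_clenches == 5

    def test_rectification(self):
        alt = np.tile([2.0, -2.0], 50)
        est = estimate_mvc([make_trace(alt, test_type="clench")])
        assert est.mvc_level == pytest.approx(2.0)

    def test_matches_mean_abs_oracle_and_permutation_invariant(self, rng):
        trials = [make_trace(rng.normal(size=200), test_type="clench")
                  for _ in range(5)]
        est = estimate_mvc(trials)
        oracle = np.mean([np.abs(t.samples).mean() for t in trials])
        assert est.mvc_level == pytest.approx(oracle)
        shuffled = estimate_mvc(trials[::-1])
        assert shuffled.mvc_level == pytest.approx(est.mvc_level)


class TestFacilitation:
    def _mvc(self):
        return estimate_mvc([make_trace(np.full(100, 1.0),
                                        test_type="clench")] * 5)

    def test_exact_target_within(self):
        trace = make_trace(np.full(100, 0.20))
        assert check_facilitation(trace, self._mvc()) == "within_target"

    def test_low_level_below(self):
        trace = make_trace(np.full(100, 0.05))
        assert check_facilitation(trace, self._mvc(), 0.25) == "below"

    def test_agrees_with_direct_inequality_oracle(self, rng):
        mvc = self._mvc()
        tol = 0.25
        for _ in range(50):
            level = rng.uniform(0, 0.6)
            trace = make_trace(np.full(100, level))
            target = 0.20 * mvc.mvc_level
            if level < target * (1 - tol):
                expected = "below"
            elif level > target * (1 + tol):
                expected = "above"
            else:
                expected = "within_target"
            assert check_facilitation(trace, mvc, tol) == expected

    def test_zero_mvc_rejected(self):
        trace = make_trace(np.full(100, 0.2))
        with pytest.raises(ValueError):
            check_facilitation(trace, estimate_mvc(
                [make_trace(np.zeros(100), test_type="clench")]))


class TestTraceIO:
    def test_roundtrip(self, tmp_path, rng):
        trace = make_trace(rng.normal(size=256), side="left",
                           test_type="MEP")
        path = tmp_path / "trace.csv"
        write_trace_csv(trace, path)
        back = read_trace_csv(path)
        np.testing.assert_allclose(back.samples, trace.samples)
        assert back.side == "left" and back.test_type == "MEP"
        assert back.sampling_rate == trace.sampling_rate

    def test_microvolt_conversion(self, tmp_path):
        path = tmp_path / "uv.csv"
        path.write_text("# sampling_rate=1000\n# window_ms=3\n"
                        "# unit=uV\nsample_mv\n100.0\n-200.0\n300.0\n")
        trace = read_trace_csv(path)
        np.testing.assert_allclose(trace.samples, [0.1, -0.2, 0.3])
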
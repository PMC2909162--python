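"""Evoked EMG waveform handling: trial averaging, peak-to-peak amplitude,
MVC estimation and facilitation-level checks.

The recordings this module represents are short evoked-response sweeps from
the masseter muscles: the jaw-jerk reflex (chin-tap, ~50 ms window) and the
trigeminal-root motor evoked potential elicited by transcranial electrical
stimulation (~20 ms window).  Multi-trial sweeps are averaged pointwise
first and the peak-to-peak amplitude is measured on the averaged trace.

All amplitudes are expressed in millivolts.  Band-pass settings of the
acquisition hardware (20-2000 Hz for the jaw jerk, 0.1-2000 Hz for the MEP)
are treated as metadata: traces are assumed to arrive already conditioned,
and no digital filtering is applied here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "EMGTrace",
    "TrialSet",
    "MVCEstimate",
    "average_trials",
    "peak_to_peak",
    "estimate_mvc",
    "check_facilitation",
    "read_trace_csv",
    "write_trace_csv",
]

Side = Literal["left", "right"]
TestType = Literal["JJ", "MEP", "clench"]

#: default facilitation target: hold background EMG at ~20% of maximal
#: voluntary contraction during intercuspal jaw-jerk trials
DEFAULT_FACILITATION_TARGET = 0.20


class DimensionalMismatchError(ValueError):
    """Trials differ in length, sampling rate, side or test type."""


@dataclass(frozen=True)
class EMGTrace:
    """One recorded EMG sweep for one muscle side.

    Parameters
    ----------
    samples
        Signed voltage samples in mV.
    sampling_rate
        Sampling frequency in Hz.
    window_ms
        Acquisition window duration in ms; must agree with
        ``len(samples) / sampling_rate`` to within one sample period.
    side
        ``"left"`` or ``"right"`` masseter.
    test_type
        ``"JJ"`` (jaw jerk), ``"MEP"`` (trigeminal-root motor evoked
        potential) or ``"clench"`` (maximal voluntary contraction trial).
    n_trials
        Number of raw trials this trace is an average of (1 for a raw sweep).
    """

    samples: np.ndarray
    sampling_rate: float
    window_ms: float
    side: Side = "right"
    test_type: TestType = "JJ"
    n_trials: int = 1

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        implied_ms = samples.size / self.sampling_rate * 1000.0
        sample_period_ms = 1000.0 / self.sampling_rate
        if abs(implied_ms - self.window_ms) > sample_period_ms:
            raise ValueError(
                f"window_ms={self.window_ms} inconsistent with "
                f"{samples.size} samples at {self.sampling_rate} Hz "
                f"(implies {implied_ms:.3f} ms)"
            )

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms from the start of the acquisition window."""
        return np.arange(self.samples.size) / self.sampling_rate * 1000.0

    def _metadata_key(self) -> tuple:
        return (self.samples.size, self.sampling_rate, self.window_ms,
                self.side, self.test_type)


@dataclass(frozen=True)
class TrialSet:
    """A homogeneous set of trials (same side, test type and dimensions)."""

    trials: tuple[EMGTrace, ...]

    def __init__(self, trials: Iterable[EMGTrace]):
        trials = tuple(trials)
        if not trials:
            raise ValueError("TrialSet requires at least one trial")
        key = trials[0]._metadata_key()
        for t in trials[1:]:
            if t._metadata_key() != key:
                raise DimensionalMismatchError(
                    "all trials must share length, sampling rate, window, "
                    "side and test type"
                )
        object.__setattr__(self, "trials", trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class MVCEstimate:
    """Maximal-voluntary-contraction level estimated from clench trials.

    ``mvc_level`` is the mean rectified (absolute-value) EMG amplitude in mV
    averaged over the clench trials.  ``facilitation_target`` is the fraction
    of MVC the subject is asked to hold during facilitated reflex trials.
    """

    mvc_level: float
    n_clenches: int
    facilitation_target: float = DEFAULT_FACILITATION_TARGET

    def __post_init__(self) -> None:
        if self.mvc_level < 0:
            raise ValueError("mvc_level must be non-negative")
        if not 0 < self.facilitation_target < 1:
            raise ValueError("facilitation_target must lie in (0, 1)")


def average_trials(trials: TrialSet | Sequence[EMGTrace]) -> EMGTrace:
    """Pointwise arithmetic mean of a set of dimensionally identical trials.

    Returns a trace with the shared metadata and ``n_trials`` set to the
    number of trials averaged.  Raises :class:`DimensionalMismatchError` if
    trials differ in length or metadata.
    """
    if not isinstance(trials, TrialSet):
        trials = TrialSet(trials)
    stack = np.stack([t.samples for t in trials])
    mean = stack.mean(axis=0)
    proto = trials.trials[0]
    return replace(proto, samples=mean, n_trials=trials.n_trials)


def _window_slice(trace: EMGTrace,
                  search_window_ms: tuple[float, float] | None) -> np.ndarray:
    if search_window_ms is None:
        return trace.samples
    lo, hi = search_window_ms
    if not lo < hi:
        raise ValueError("search window must have positive width")
    if lo < 0 or hi > trace.window_ms:
        raise ValueError(
            f"search window [{lo}, {hi}] ms outside acquisition window "
            f"[0, {trace.window_ms}] ms"
        )
    t = trace.times_ms
    mask = (t >= lo) & (t <= hi)
    segment = trace.samples[mask]
    if segment.size == 0:
        raise ValueError("search window contains no samples")
    return segment


def peak_to_peak(trace: EMGTrace,
                 search_window_ms: tuple[float, float] | None = None) -> float:
    """Peak-to-peak amplitude in mV: max minus min over the search window.

    The search window defaults to the full acquisition window; a
    post-stimulus sub-window ``(lo_ms, hi_ms)`` may be given to exclude a
    stimulus artifact.  The result is always >= 0.
    """
    segment = _window_slice(trace, search_window_ms)
    return float(segment.max() - segment.min())


def estimate_mvc(clench_traces: TrialSet | Sequence[EMGTrace],
                 facilitation_target: float = DEFAULT_FACILITATION_TARGET,
                 ) -> MVCEstimate:
    """Estimate the MVC level from maximal-clench trials.

    The level is the mean over trials of the mean rectified sample
    amplitude.  Rectified mean (not RMS) is used; see the methods note.
    """
    if not isinstance(clench_traces, TrialSet):
        clench_traces = TrialSet(clench_traces)
    per_trial = [float(np.abs(t.samples).mean()) for t in clench_traces]
    return MVCEstimate(
        mvc_level=float(np.mean(per_trial)),
        n_clenches=clench_traces.n_trials,
        facilitation_target=facilitation_target,
    )


def check_facilitation(trace: EMGTrace, mvc: MVCEstimate,
                       tolerance_frac: float = 0.25) -> str:
    """Classify a trace's background EMG level against the MVC target.

    Compares the trace's mean rectified amplitude with
    ``facilitation_target * mvc_level`` and returns ``"within_target"``,
    ``"below"`` or ``"above"`` using a relative tolerance band of
    ``tolerance_frac`` around the target.
    """
    if mvc.mvc_level <= 0:
        raise ValueError("MVC level must be positive to check facilitation")
    level = float(np.abs(trace.samples).mean())
    target = mvc.facilitation_target * mvc.mvc_level
    if level < target * (1 - tolerance_frac):
        return "below"
    if level > target * (1 + tolerance_frac):
        return "above"
    return "within_target"


# ---------------------------------------------------------------------------
# trace file I/O: delimited text with a small header carrying metadata
# ---------------------------------------------------------------------------

_HEADER_FIELDS = ("sampling_rate", "window_ms", "side", "test_type",
                  "n_trials", "unit")


def write_trace_csv(trace: EMGTrace, path: str | Path) -> None:
    """Write a trace as CSV: ``# key=value`` header lines, then one sample
    per line in mV."""
    lines = [
        f"# sampling_rate={trace.sampling_rate}",
        f"# window_ms={trace.window_ms}",
        f"# side={trace.side}",
        f"# test_type={trace.test_type}",
        f"# n_trials={trace.n_trials}",
        "# unit=mV",
        "sample_mv",
    ]
    lines += [repr(float(s)) for s in trace.samples]
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_csv(path: str | Path) -> EMGTrace:
    """Read a trace written by :func:`write_trace_csv`.

    Inputs recorded in microvolts (``unit=uV`` header) are converted to mV
    on load.
    """
    meta: dict[str, str] = {}
    samples: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            elif line != "sample_mv":
                samples.append(float(line))
    unit = meta.get("unit", "mV")
    scale = 1e-3 if unit in ("uV", "µV", "μV") else 1.0
    return EMGTrace(
        samples=np.asarray(samples) * scale,
        sampling_rate=float(meta["sampling_rate"]),
        window_ms=float(meta["window_ms"]),
        side=meta.get("side", "right"),  # type: ignore[arg-type]
        test_type=meta.get("test_type", "JJ"),  # type: ignore[arg-type]
        n_trials=int(meta.get("n_trials", 1)),
    )
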
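"""Cohort-level descriptive statistics for asymmetry ratios.

Covers the descriptive grid reported for the control and patient cohorts
(mean, SD, median, variance, skewness, kurtosis, difference between means),
the percentile table used to derive screening cutoffs, and the two-sided
Mann-Whitney U test for intergroup comparison of the ratio distributions.

Conventions
-----------
* variance and SD use the n-1 (sample) denominator;
* skewness is the adjusted Fisher-Pearson standardized third moment
  (``scipy.stats.skew(bias=False)``);
* kurtosis is EXCESS kurtosis (Fisher convention, 0 for a normal), the only
  convention under which published cohort values such as -1.1 are possible;
* percentiles use linear interpolation between closest ranks by default;
  the raw lower-order-statistic convention is available because with small
  reference cohorts (n ~ 36) the two differ materially at the 5th
  percentile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSummary",
    "PercentileTable",
    "MannWhitneyResult",
    "summarize",
    "percentile",
    "mann_whitney",
    "build_table1",
    "build_percentile_table",
    "STANDARD_PROBES",
]

#: percentile probes used for cutoff derivation
STANDARD_PROBES = (5, 10, 25, 50, 75, 90, 95)

PercentileMethod = Literal["linear", "lower"]

#: combined-sample-size bound below which the exact Mann-Whitney null
#: distribution is enumerated (ties force the normal approximation)
EXACT_MW_BOUND = 20


class InsufficientDataError(ValueError):
    """Fewer observations than the statistic requires."""


@dataclass(frozen=True)
class CohortSummary:
    """Moment summary of one cohort's ratio values.

    ``skewness`` and ``kurtosis`` are NaN for degenerate (constant) samples,
    where the standardized moments are undefined.
    """

    n: int
    mean: float
    sd: float
    median: float
    variance: float
    skewness: float
    kurtosis: float
    group: str = ""
    measure: str = ""


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    method: Literal["exact_enumeration", "normal_approx_tie_corrected"]


@dataclass(frozen=True)
class PercentileTable:
    """Percentile grid per (group, measure); values non-decreasing in probe."""

    probes: tuple[int, ...]
    values: pd.DataFrame  # index: probes; columns: (group, measure)


def summarize(values: Sequence[float], group: str = "",
              measure: str = "") -> CohortSummary:
    """Compute the full moment summary for one cohort."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 observations")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        skew = kurt = math.nan  # standardized moments undefined
    else:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return CohortSummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=sd,
        median=float(np.median(x)),
        variance=sd ** 2,
        skewness=skew,
        kurtosis=kurt,
        group=group,
        measure=measure,
    )


def percentile(values: Sequence[float], probe: float,
               method: PercentileMethod = "linear") -> float:
    """Order-statistic percentile of a sample.

    ``method="linear"`` interpolates between closest ranks (the common
    scientific-software default); ``method="lower"`` returns the raw order
    statistic at or below the probe.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    if not 0 < probe < 100:
        raise ValueError("probe must lie strictly between 0 and 100")
    np_method = "linear" if method == "linear" else "lower"
    return float(np.percentile(x, probe, method=np_method))


def mann_whitney(a: Sequence[float], b: Sequence[float],
                 exact_bound: int = EXACT_MW_BOUND) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test for two independent samples.

    The exact null distribution is enumerated when the combined sample size
    is at most ``exact_bound`` and there are no ties; otherwise the
    tie-corrected normal approximation is used.  The reported U statistic is
    the count of (a, b) pairs where the first-sample value wins (ties count
    one half).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    use_exact = (a.size + b.size) <= exact_bound and not has_ties
    scipy_method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method=scipy_method)
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=("exact_enumeration" if use_exact
                else "normal_approx_tie_corrected"),
    )


def build_table1(control: Sequence[float], tmd: Sequence[float],
                 measure: str = "") -> pd.DataFrame:
    """Descriptive comparison of a control and a patient cohort.

    Returns a tidy frame with one column per group plus the difference
    between means (control minus patient) and the two-sided Mann-Whitney
    p-value, mirroring the standard baseline-characteristics layout.
    """
    s_ctrl = summarize(control, group="control", measure=measure)
    s_tmd = summarize(tmd, group="TMD", measure=measure)
    mw = mann_whitney(control, tmd)
    rows = ["n", "mean", "sd", "median", "variance", "skewness", "kurtosis"]
    frame = pd.DataFrame(
        {
            "TMD": [getattr(s_tmd, r) for r in rows],
            "control": [getattr(s_ctrl, r) for r in rows],
        },
        index=rows,
    )
    frame.attrs["measure"] = measure
    frame.attrs["difference_between_means"] = s_ctrl.mean - s_tmd.mean
    frame.attrs["mann_whitney"] = mw
    return frame


def build_percentile_table(cohorts: dict[tuple[str, str], Sequence[float]],
                           probes: Sequence[int] = STANDARD_PROBES,
                           method: PercentileMethod = "linear",
                           ) -> PercentileTable:
    """Percentile grid for several (group, measure) cohorts at once."""
    data = {
        key: [percentile(vals, p, method=method) for p in probes]
        for key, vals in cohorts.items()
    }
    frame = pd.DataFrame(data, index=list(probes))
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["group", "measure"])
    return PercentileTable(probes=tuple(probes), values=frame)
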
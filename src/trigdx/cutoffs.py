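"""Screening-threshold derivation from a control cohort.

Two thresholds drive the diagnostic screen:

* **cutoff a** — the control-cohort 5th percentile of the trigeminal-MEP
  asymmetry ratio (bR-MEPs%).  A patient whose MEP ratio falls below it is
  flagged for organic trigeminal damage.  Published value: 0.76.
* **cutoff b** — the control-cohort 5th percentile of the intercuspal
  jaw-jerk asymmetry ratio (ipJJ%).  Below it indicates a temporomandibular
  disorder; at or above it, orofacial pain of other origin.  Published
  value: 0.32.

The published pair ships as a frozen default (the reference cohort's raw
data is not publicly available); deriving new cutoffs from a user-supplied
control cohort is an explicit opt-in via :func:`derive_cutoffs`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort_stats import PercentileMethod, percentile

__all__ = [
    "CutoffPair",
    "derive_cutoffs",
    "published_cutoffs",
    "bootstrap_cutoff_ci",
    "PUBLISHED_CUTOFF_A",
    "PUBLISHED_CUTOFF_B",
]

PUBLISHED_CUTOFF_A = 0.76
PUBLISHED_CUTOFF_B = 0.32


@dataclass(frozen=True)
class CutoffPair:
    """The two screening thresholds with derivation provenance."""

    cutoff_a: float  # bR-MEPs% threshold (organic-damage screen)
    cutoff_b: float  # ipJJ% threshold (TMD/OP discriminator)
    percentile_used: float = 5.0
    provenance: str = "published"
    n_control: int | None = None

    def __post_init__(self) -> None:
        if not (self.cutoff_a > 0 and self.cutoff_b > 0):
            raise ValueError("cutoffs must be positive")
        if not 0 < self.percentile_used < 100:
            raise ValueError("percentile_used must lie in (0, 100)")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CutoffPair":
        return cls(**json.loads(Path(path).read_text()))


def published_cutoffs() -> CutoffPair:
    """The published screening thresholds (0.76, 0.32), both the control
    cohort's 5th percentile of the respective ratio."""
    return CutoffPair(
        cutoff_a=PUBLISHED_CUTOFF_A,
        cutoff_b=PUBLISHED_CUTOFF_B,
        percentile_used=5.0,
        provenance="published",
        n_control=36,
    )


def derive_cutoffs(control_mep_ratios: Sequence[float],
                   control_jj_ratios: Sequence[float],
                   percentile_probe: float = 5.0,
                   method: PercentileMethod = "linear",
                   cohort_id: str = "user_cohort") -> CutoffPair:
    """Derive both thresholds as a percentile of a control cohort's ratios.

    ``method`` selects the percentile convention ("linear" interpolation or
    the raw "lower" order statistic) — with typical control cohort sizes
    the choice shifts the 5th percentile noticeably.
    """
    a = percentile(control_mep_ratios, percentile_probe, method=method)
    b = percentile(control_jj_ratios, percentile_probe, method=method)
    n = min(len(control_mep_ratios), len(control_jj_ratios))
    return CutoffPair(
        cutoff_a=a,
        cutoff_b=b,
        percentile_used=percentile_probe,
        provenance=f"derived:{cohort_id}:{method}",
        n_control=n,
    )


def bootstrap_cutoff_ci(control_ratios: Sequence[float],
                        percentile_probe: float = 5.0,
                        n_boot: int = 2000,
                        ci: float = 0.95,
                        seed: int | None = None,
                        method: PercentileMethod = "linear",
                        ) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for one derived cutoff.

    Extension utility — the screening model itself uses the plain
    percentile with no resampling.
    """
    x = np.asarray(control_ratios, dtype=float)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        resample = rng.choice(x, size=x.size, replace=True)
        boots[i] = percentile(resample, percentile_probe, method=method)
    alpha = (1 - ci) / 2
    return (float(np.quantile(boots, alpha)),
            float(np.quantile(boots, 1 - alpha)))
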
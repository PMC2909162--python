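"""Model/Results interface over the cutoff-derivation and screening pipeline.

:class:`DiagnosticCutoffModel` is constructed from a control cohort's
asymmetry ratios (or from subject records whose ratios it computes) and is
"fitted" by estimating the screening thresholds as a low percentile of the
control distributions.  :meth:`~DiagnosticCutoffModel.fit` returns a
:class:`DiagnosticCutoffResults` carrying the cutoff pair, per-measure
moment summaries, the full percentile grid, optional bootstrap confidence
intervals for the cutoffs, and a ``summary()`` table; subject
classification and cohort simulation hang off the results object.

With no control data the model falls back to the published thresholds
(0.76 / 0.32), which is the recommended mode for clinical screening since
the published reference cohort cannot be reconstituted.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .asymmetry import BilateralAmplitudes, side_ratio
from .classifier import (DiagnosticResult, SubjectRecord, classify,
                         classify_cohort, results_to_frame)
from .cohort_stats import (PercentileMethod, PercentileTable,
                           build_percentile_table, summarize)
from .cutoffs import (CutoffPair, bootstrap_cutoff_ci, derive_cutoffs,
                      published_cutoffs)
from . import synthdata

__all__ = ["DiagnosticCutoffModel", "DiagnosticCutoffResults"]


class DiagnosticCutoffModel:
    """Percentile-threshold screening model for trigeminal asymmetry ratios.

    Parameters
    ----------
    control_mep_ratios, control_jj_ratios
        Control-cohort asymmetry ratios (reference side over contralateral)
        for the trigeminal MEP and the intercuspal jaw jerk.  Pass ``None``
        for both to use the published thresholds without refitting.
    percentile_probe
        Percentile of the control distribution taken as threshold
        (default 5).
    method
        Percentile convention, ``"linear"`` interpolation or the raw
        ``"lower"`` order statistic.
    """

    def __init__(self,
                 control_mep_ratios: Sequence[float] | None = None,
                 control_jj_ratios: Sequence[float] | None = None,
                 percentile_probe: float = 5.0,
                 method: PercentileMethod = "linear"):
        if (control_mep_ratios is None) != (control_jj_ratios is None):
            raise ValueError(
                "provide both control ratio samples or neither")
        self.control_mep_ratios = (None if control_mep_ratios is None
                                   else np.asarray(control_mep_ratios, float))
        self.control_jj_ratios = (None if control_jj_ratios is None
                                  else np.asarray(control_jj_ratios, float))
        self.percentile_probe = percentile_probe
        self.method: PercentileMethod = method

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame,
                       mep_col: str = "mep_ratio",
                       jj_col: str = "jj_ratio",
                       **kwargs) -> "DiagnosticCutoffModel":
        """Build from a DataFrame with one ratio pair per control subject."""
        return cls(data[mep_col].to_numpy(), data[jj_col].to_numpy(),
                   **kwargs)

    @classmethod
    def from_subject_records(cls, records: Sequence[SubjectRecord],
                             **kwargs) -> "DiagnosticCutoffModel":
        """Build from control subject records, computing their ratios."""
        mep, jj = [], []
        for r in records:
            mep.append(side_ratio(BilateralAmplitudes(
                r.mep_ref, r.mep_contra, r.reference_side_kind, "MEP")).value)
            jj.append(side_ratio(BilateralAmplitudes(
                r.jj_ip_ref, r.jj_ip_contra, r.reference_side_kind,
                "JJ_intercuspal")).value)
        return cls(mep, jj, **kwargs)

    @classmethod
    def simulate_control(cls, n: int = 36, seed: int = 0,
                         **kwargs) -> "DiagnosticCutoffModel":
        """Build from a synthetic control cohort at the published ratio
        moments (moment-matched skew-normal per measure)."""
        mep = synthdata.sample_ratios(
            synthdata.TABLE1_RATIO_SPECS[("control", "bR-MEPs%")], n, seed)
        jj = synthdata.sample_ratios(
            synthdata.TABLE1_RATIO_SPECS[("control", "ipJJ%")], n, seed + 1)
        return cls(mep, jj, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self, bootstrap: bool = False, n_boot: int = 2000,
            seed: int | None = None) -> "DiagnosticCutoffResults":
        """Estimate the cutoff pair (or adopt the published one).

        With control data, both cutoffs are the ``percentile_probe``-th
        percentile of the respective ratio sample; ``bootstrap=True`` adds
        95% percentile-bootstrap intervals.
        """
        if self.control_mep_ratios is None:
            return DiagnosticCutoffResults(self, published_cutoffs(),
                                           None, None, None, None, None)
        cutoffs = derive_cutoffs(self.control_mep_ratios,
                                 self.control_jj_ratios,
                                 percentile_probe=self.percentile_probe,
                                 method=self.method)
        mep_summary = summarize(self.control_mep_ratios,
                                group="control", measure="bR-MEPs%")
        jj_summary = summarize(self.control_jj_ratios,
                               group="control", measure="ipJJ%")
        ptable = build_percentile_table(
            {("control", "bR-MEPs%"): self.control_mep_ratios,
             ("control", "ipJJ%"): self.control_jj_ratios},
            method=self.method)
        ci_a = ci_b = None
        if bootstrap:
            ci_a = bootstrap_cutoff_ci(self.control_mep_ratios,
                                       self.percentile_probe, n_boot,
                                       seed=seed, method=self.method)
            ci_b = bootstrap_cutoff_ci(self.control_jj_ratios,
                                       self.percentile_probe, n_boot,
                                       seed=None if seed is None else seed + 1,
                                       method=self.method)
        return DiagnosticCutoffResults(self, cutoffs, mep_summary,
                                       jj_summary, ptable, ci_a, ci_b)


class DiagnosticCutoffResults:
    """Fitted screening thresholds with diagnostics and classification."""

    def __init__(self, model: DiagnosticCutoffModel, cutoffs: CutoffPair,
                 mep_summary, jj_summary, percentiles: PercentileTable | None,
                 cutoff_a_ci, cutoff_b_ci):
        self.model = model
        self.cutoffs = cutoffs
        self.mep_summary = mep_summary
        self.jj_summary = jj_summary
        self.percentiles = percentiles
        self.cutoff_a_ci = cutoff_a_ci
        self.cutoff_b_ci = cutoff_b_ci

    # -- application ------------------------------------------------------

    def classify(self, record: SubjectRecord) -> DiagnosticResult:
        """Run the two-step screen on one subject with these cutoffs."""
        return classify(record, self.cutoffs)

    def classify_cohort(self, records: Sequence[SubjectRecord]):
        """Classify a cohort; returns (per-record results, label table)."""
        return classify_cohort(records, self.cutoffs)

    def predict(self, data: pd.DataFrame) -> pd.DataFrame:
        """Classify subjects given as a DataFrame of amplitude columns.

        Expects columns ``subject_id, jj_ip_ref, jj_ip_contra, mep_ref,
        mep_contra`` (extra columns ignored); returns the flattened results
        frame.
        """
        records = [
            SubjectRecord(
                subject_id=str(row.get("subject_id", i)),
                jj_ip_ref=float(row["jj_ip_ref"]),
                jj_ip_contra=float(row["jj_ip_contra"]),
                mep_ref=float(row["mep_ref"]),
                mep_contra=float(row["mep_contra"]),
            )
            for i, row in data.iterrows()
        ]
        results, _ = classify_cohort(records, self.cutoffs)
        return results_to_frame(r for r in results
                                if isinstance(r, DiagnosticResult))

    def simulate_cohort(self, group: str = "TMD", n: int = 33,
                        seed: int = 0) -> list[SubjectRecord]:
        """Draw a synthetic cohort at the published amplitude statistics."""
        return synthdata.sample_subjects(
            synthdata.AMPLITUDE_SPECS[group], n, seed)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary table of the fitted thresholds."""
        lines = [
            "Trigeminal asymmetry screening thresholds",
            "=" * 57,
            f"provenance:        {self.cutoffs.provenance}",
            f"percentile used:   {self.cutoffs.percentile_used:g}th "
            "(control cohort)",
            f"n control:         {self.cutoffs.n_control}",
            "-" * 57,
            f"cutoff a (bR-MEPs%, organic-damage screen):  "
            f"{self.cutoffs.cutoff_a:.3f}",
            f"cutoff b (ipJJ%, TMD/OP discriminator):      "
            f"{self.cutoffs.cutoff_b:.3f}",
        ]
        if self.cutoff_a_ci is not None:
            lines.append(f"cutoff a 95% bootstrap CI: "
                         f"({self.cutoff_a_ci[0]:.3f}, "
                         f"{self.cutoff_a_ci[1]:.3f})")
        if self.cutoff_b_ci is not None:
            lines.append(f"cutoff b 95% bootstrap CI: "
                         f"({self.cutoff_b_ci[0]:.3f}, "
                         f"{self.cutoff_b_ci[1]:.3f})")
        if self.mep_summary is not None:
            lines.append("-" * 57)
            for s in (self.mep_summary, self.jj_summary):
                lines.append(
                    f"{s.measure:10s} n={s.n:4d}  mean={s.mean:.3f}  "
                    f"sd={s.sd:.3f}  median={s.median:.3f}  "
                    f"skew={s.skewness:.2f}")
        lines.append("=" * 57)
        lines.append("decision rule: MEP ratio < cutoff a -> ORGANIC_DAMAGE;")
        lines.append("else JJ ratio < cutoff b -> TMD, otherwise OP "
                     "(equality passes).")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<DiagnosticCutoffResults cutoff_a={self.cutoffs.cutoff_a:.3f} "
                f"cutoff_b={self.cutoffs.cutoff_b:.3f} "
                f"provenance={self.cutoffs.provenance!r}>")
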
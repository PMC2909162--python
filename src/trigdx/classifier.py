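"""Two-step matrix classifier for trigeminal electrophysiology screening.

Step 1 screens the trigeminal-MEP asymmetry ratio (bR-MEPs%) against
cutoff a: a ratio below the cutoff indicates organic damage to the
trigeminal motor pathway and the subject exits the model immediately.
Step 2, reached only on a step-1 pass, screens the intercuspal jaw-jerk
ratio (ipJJ%) against cutoff b: below the cutoff the failed reflex
facilitation on the painful side indicates a temporomandibular disorder
(TMD); at or above it the pain is classified as orofacial pain of other
origin (OP) — a patient who must not be mistaken for healthy.

Boundary convention: a ratio exactly equal to a cutoff PASSES the screen
at both steps (>= is a pass).  The model is defined only for subjects
presenting with pain; there is no "healthy" label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Sequence

import pandas as pd

from .asymmetry import (AbsentResponseError, BilateralAmplitudes,
                        side_ratio)
from .cutoffs import CutoffPair, published_cutoffs

__all__ = [
    "Label",
    "SubjectRecord",
    "DiagnosticResult",
    "IndeterminateResponseError",
    "classify",
    "classify_cohort",
]


class Label(str, Enum):
    ORGANIC_DAMAGE = "ORGANIC_DAMAGE"
    TMD = "TMD"
    OP = "OP"


class IndeterminateResponseError(ValueError):
    """Absent contralateral jaw-jerk after a step-1 pass: the step-2 ratio
    is undefined and the case must be resolved clinically, not guessed."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's bilateral amplitudes (mV) and screening metadata."""

    subject_id: str
    jj_ip_ref: float
    jj_ip_contra: float
    mep_ref: float
    mep_contra: float
    group: Literal["control", "TMD", "unknown"] = "unknown"
    reference_side: Literal["left", "right"] = "right"
    reference_side_kind: Literal["pain_side", "non_preferred_side"] = "pain_side"

    def __post_init__(self) -> None:
        for name in ("jj_ip_ref", "jj_ip_contra", "mep_ref", "mep_contra"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class DiagnosticResult:
    """Outcome of the two-step screen for one subject.

    ``jj_ratio`` is None when step 1 fails (the jaw-jerk ratio is never
    evaluated for organic-damage cases).  ``absent_response`` marks a
    step-1 failure caused by a missing contralateral MEP rather than a
    measured ratio.
    """

    subject_id: str
    mep_ratio: float | None
    jj_ratio: float | None
    label: Label
    step_reached: int
    cutoffs_used: CutoffPair
    absent_response: bool = False


def classify(record: SubjectRecord,
             cutoffs: CutoffPair | None = None) -> DiagnosticResult:
    """Run the two-step screen on one subject.

    A zero contralateral MEP amplitude (no evoked response at all) is
    treated as maximal asymmetry: the subject fails step 1 and is labeled
    ORGANIC_DAMAGE with the ``absent_response`` flag set.  A zero
    contralateral jaw-jerk after a step-1 pass raises
    :class:`IndeterminateResponseError`.
    """
    if cutoffs is None:
        cutoffs = published_cutoffs()

    try:
        mep_ratio = side_ratio(BilateralAmplitudes(
            record.mep_ref, record.mep_contra,
            record.reference_side_kind, "MEP")).value
    except AbsentResponseError:
        return DiagnosticResult(
            subject_id=record.subject_id,
            mep_ratio=None, jj_ratio=None,
            label=Label.ORGANIC_DAMAGE, step_reached=1,
            cutoffs_used=cutoffs, absent_response=True,
        )

    if mep_ratio < cutoffs.cutoff_a:
        return DiagnosticResult(
            subject_id=record.subject_id,
            mep_ratio=mep_ratio, jj_ratio=None,
            label=Label.ORGANIC_DAMAGE, step_reached=1,
            cutoffs_used=cutoffs,
        )

    try:
        jj_ratio = side_ratio(BilateralAmplitudes(
            record.jj_ip_ref, record.jj_ip_contra,
            record.reference_side_kind, "JJ_intercuspal")).value
    except AbsentResponseError as err:
        raise IndeterminateResponseError(
            f"subject {record.subject_id}: step 1 passed but the "
            "contralateral jaw-jerk response is absent; the step-2 ratio "
            "is undefined"
        ) from err

    label = Label.TMD if jj_ratio < cutoffs.cutoff_b else Label.OP
    return DiagnosticResult(
        subject_id=record.subject_id,
        mep_ratio=mep_ratio, jj_ratio=jj_ratio,
        label=label, step_reached=2,
        cutoffs_used=cutoffs,
    )


def classify_cohort(records: Sequence[SubjectRecord],
                    cutoffs: CutoffPair | None = None,
                    ) -> tuple[list[DiagnosticResult | Exception],
                               pd.DataFrame]:
    """Classify a cohort, collecting per-record errors instead of raising.

    Returns the per-record results in input order (an entry is the caught
    exception for indeterminate cases) and a label frequency table with
    counts and proportions over the successfully classified records.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    if cutoffs is None:
        cutoffs = published_cutoffs()

    results: list[DiagnosticResult | Exception] = []
    for rec in records:
        try:
            results.append(classify(rec, cutoffs))
        except (IndeterminateResponseError, ValueError) as err:
            results.append(err)

    labels = [r.label.value for r in results
              if isinstance(r, DiagnosticResult)]
    counts = pd.Series(labels, dtype="object").value_counts()
    freq = pd.DataFrame({
        "count": counts,
        "proportion": counts / max(len(labels), 1),
    }).reindex([l.value for l in Label], fill_value=0)
    freq["proportion"] = freq["proportion"].astype(float)
    return results, freq


def results_to_frame(results: Iterable[DiagnosticResult]) -> pd.DataFrame:
    """Flatten diagnostic results into a DataFrame for export."""
    rows = []
    for r in results:
        if not isinstance(r, DiagnosticResult):
            continue
        rows.append({
            "subject_id": r.subject_id,
            "mep_ratio": r.mep_ratio,
            "jj_ratio": r.jj_ratio,
            "label": r.label.value,
            "step_reached": r.step_reached,
            "cutoff_a": r.cutoffs_used.cutoff_a,
            "cutoff_b": r.cutoffs_used.cutoff_b,
            "absent_response": r.absent_response,
        })
    return pd.DataFrame(rows)
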
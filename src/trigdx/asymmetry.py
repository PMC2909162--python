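"""Bilateral asymmetry ratios for evoked trigeminal responses.

The central quantity of the screening model is the ratio of the evoked
response amplitude on the *reference* side to the contralateral side:

    ratio = A_reference / A_contralateral

The reference side is the painful side in patients and the non-preferred
masticatory side in controls, and it is ALWAYS the numerator — the ratio is
deliberately not folded to min/max, so values above 1 occur (the reference
side can be the larger one) and are meaningful.  The symbols used in the
field are bR-MEPs% for the motor-evoked-potential ratio and ipJJ% (rpJJ%)
for the jaw-jerk ratio in intercuspal (rest) position; despite the "%"
notation, values are stored as dimensionless fractions.

A ratio r <= 1 maps onto a "between-side skewness" percentage
(1 - r) * 100: the screening cutoff 0.76 corresponds to 24% asymmetry, and
0.32 to 68%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = [
    "BilateralAmplitudes",
    "AsymmetryRatio",
    "AbsentResponseError",
    "side_ratio",
    "jj_to_mep_fraction",
    "skewness_percent",
]

ReferenceSideKind = Literal["pain_side", "non_preferred_side"]
RatioTestType = Literal["JJ_intercuspal", "JJ_rest", "MEP"]


class AbsentResponseError(ZeroDivisionError):
    """Contralateral amplitude is zero: no evoked response on that side.

    An absent contralateral response makes the ratio undefined; the
    classifier treats it as maximal asymmetry (step-1 fail) rather than
    propagating an infinity.
    """


@dataclass(frozen=True)
class BilateralAmplitudes:
    """Paired peak-to-peak amplitudes (mV) for one test type."""

    reference_amplitude: float
    contralateral_amplitude: float
    reference_side_kind: ReferenceSideKind = "pain_side"
    test_type: RatioTestType = "MEP"

    def __post_init__(self) -> None:
        if self.reference_amplitude < 0 or self.contralateral_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class AsymmetryRatio:
    """Reference-over-contralateral amplitude ratio (dimensionless)."""

    value: float
    test_type: RatioTestType = "MEP"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("ratio must be non-negative")


def side_ratio(b: BilateralAmplitudes) -> AsymmetryRatio:
    """Reference-side amplitude divided by contralateral amplitude.

    Raises :class:`AbsentResponseError` when the contralateral amplitude is
    zero (absent response; see the classifier's handling).
    """
    if b.contralateral_amplitude == 0:
        raise AbsentResponseError(
            "contralateral amplitude is zero — absent evoked response"
        )
    return AsymmetryRatio(
        value=b.reference_amplitude / b.contralateral_amplitude,
        test_type=b.test_type,
    )


def jj_to_mep_fraction(jj_amp: float, mep_amp: float) -> float:
    """Jaw-jerk amplitude as a fraction of the ipsilateral MEP amplitude.

    In TMD patients this facilitation index drops to ~9.5% on the painful
    side versus ~29% contralaterally, reflecting failed reflex facilitation
    rather than motor-fiber damage.
    """
    if mep_amp <= 0:
        raise ZeroDivisionError("MEP amplitude must be positive")
    if jj_amp < 0:
        raise ValueError("JJ amplitude must be non-negative")
    return jj_amp / mep_amp


def skewness_percent(ratio: AsymmetryRatio | float) -> float:
    """Between-side skewness percentage implied by a ratio: (1 - r) * 100.

    Negative when the reference side is the larger one (r > 1).
    """
    value = ratio.value if isinstance(ratio, AsymmetryRatio) else float(ratio)
    if value < 0:
        raise ValueError("ratio must be non-negative")
    return (1.0 - value) * 100.0
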
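"""CPT protocol logic: symptom scoring, titration stop rule, CAP classes
and sensitivity categories.

The summation symptom score (SSS) sums four symptom grades — tearing,
itching, irritation and redness, each rated 0 (none) to 3 (strong) — to a
value in 0..12.  The titration applies allergen dilutions in the fixed
order 1:1000, 1:100, 1:10, stock, after a negative control-solution check,
stopping immediately after the first reactive dilution.  Serum
allergen-specific IgE (kU/L) is banded into ordinal CAP classes 0-6.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .session import DILUTIONS

__all__ = [
    "SYMPTOMS",
    "SymptomRecord",
    "compute_sss",
    "TitrationResult",
    "run_titration",
    "CAP_BOUNDARIES",
    "CapClass",
    "cap_class",
    "RULES",
    "SensitivityCategory",
    "sensitivity_category",
    "check_inclusion",
]

SYMPTOMS = ("tearing", "itching", "irritation", "redness")

#: Conventional CAP-class ladder for sIgE in kU/L; configurable because the
#: banding is a reporting convention, not part of the measurement itself.
#: Class = number of boundaries at or below the concentration (half-open
#: intervals, a concentration equal to a boundary joins the upper class).
CAP_BOUNDARIES = (0.35, 0.7, 3.5, 17.5, 50.0, 100.0)

#: Minimum sIgE for study inclusion.  Note this floor lies below the CAP
#: class-1 lower boundary (0.35 kU/L), so included patients can carry CAP
#: class 0; the validator flags but does not reject them.
INCLUSION_MIN_SIGE = 0.01


@dataclass(frozen=True)
class SymptomRecord:
    """Grades of the four CPT symptoms at one timepoint, each 0-3."""

    tearing: int
    itching: int
    irritation: int
    redness: int

    def __post_init__(self) -> None:
        for name in SYMPTOMS:
            grade = getattr(self, name)
            if not isinstance(grade, (int,)) or grade not in (0, 1, 2, 3):
                raise ValueError(f"symptom {name!r} grade {grade!r} not in {{0,1,2,3}}")

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in SYMPTOMS)


def compute_sss(rec: SymptomRecord) -> int:
    """Summation symptom score: sum of the four grades, range 0-12."""
    return int(sum(rec.as_tuple()))


@dataclass
class TitrationResult:
    """Dilution measurements actually performed under the stop rule."""

    performed: tuple
    reacted_at: Optional[str]
    aborted_on_control: bool = False

    @property
    def n_measurements(self) -> int:
        return len(self.performed)


def run_titration(
    outcome: Callable[[str], bool], control_reactive: bool = False
) -> TitrationResult:
    """Run the titration protocol against a per-dilution outcome oracle.

    ``outcome(dilution)`` answers whether the reaction at that dilution is
    observed.  Dilutions are applied in increasing concentration; the
    protocol stops immediately after the first reactive dilution or once
    the stock solution has been applied.  A reaction to the control
    solution aborts the session, which is then invalid for allergen
    scoring.
    """
    if control_reactive:
        return TitrationResult(performed=(), reacted_at=None, aborted_on_control=True)
    performed = []
    reacted_at = None
    for dilution in DILUTIONS:
        performed.append(dilution)
        if outcome(dilution):
            reacted_at = dilution
            break
    return TitrationResult(performed=tuple(performed), reacted_at=reacted_at)


@dataclass(frozen=True)
class CapClass:
    sige_ku_per_l: float
    cap_class: int


def cap_class(sige: float, boundaries: Sequence[float] = CAP_BOUNDARIES) -> CapClass:
    """Band an sIgE concentration (kU/L) into its ordinal CAP class."""
    if sige < 0:
        raise ValueError("sIgE concentration cannot be negative")
    boundaries = tuple(boundaries)
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValueError("CAP boundaries must be strictly increasing")
    cls = sum(sige >= b for b in boundaries)
    return CapClass(sige_ku_per_l=float(sige), cap_class=int(cls))


RULES = ("sss", "redness", "combined_human", "instrument")

#: Rule firing conditions: SSS of 3 or higher; human redness grade above 1;
#: either of the two (the combined human criterion); instrument score above
#: the classification threshold.
SSS_POSITIVE = 3
REDNESS_POSITIVE_ABOVE = 1


@dataclass(frozen=True)
class SensitivityCategory:
    """Weakest dilution at which the selected positivity rule fired.

    ``category`` is one of the dilution labels or ``"none"`` if the rule
    never fired.
    """

    category: str
    rule_used: str


def sensitivity_category(
    dilutions: Sequence[str],
    sss: Optional[Sequence[int]] = None,
    redness_grades: Optional[Sequence[int]] = None,
    scores: Optional[Sequence[float]] = None,
    rule: str = "combined_human",
    threshold: float = 0.3,
) -> SensitivityCategory:
    """Assign the sensitivity category under one positivity rule.

    Inputs are dilution-ordered, one entry per performed measurement.  The
    category is the first dilution at which the rule fires; ``"none"`` if
    it never does.
    """
    dilutions = list(dilutions)
    if not dilutions:
        raise ValueError("empty dilution sequence")
    order = [DILUTIONS.index(d) for d in dilutions]
    if order != sorted(order) or len(set(order)) != len(order):
        raise ValueError("dilutions must be unique and in titration order")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")

    def fired(i: int) -> bool:
        if rule == "sss":
            return sss[i] >= SSS_POSITIVE
        if rule == "redness":
            return redness_grades[i] > REDNESS_POSITIVE_ABOVE
        if rule == "combined_human":
            return sss[i] >= SSS_POSITIVE or redness_grades[i] > REDNESS_POSITIVE_ABOVE
        return scores[i] > threshold

    needed = {
        "sss": (sss,),
        "redness": (redness_grades,),
        "combined_human": (sss, redness_grades),
        "instrument": (scores,),
    }[rule]
    if any(v is None for v in needed):
        raise ValueError(f"rule {rule!r} requires inputs that were not provided")
    for seq in needed:
        if len(seq) != len(dilutions):
            raise ValueError("per-dilution inputs must match the dilution sequence")

    for i, dilution in enumerate(dilutions):
        if fired(i):
            return SensitivityCategory(category=dilution, rule_used=rule)
    return SensitivityCategory(category="none", rule_used=rule)


def check_inclusion(sige: float, min_sige: float = INCLUSION_MIN_SIGE) -> dict:
    """Record the sIgE inclusion criterion verdict for one patient.

    Returns a dict with ``included`` and an ``anomalous_floor`` note: the
    protocol floor sits below the CAP class-1 boundary, so inclusion does
    not guarantee a nonzero CAP class.
    """
    return {
        "included": sige > min_sige,
        "min_sige": min_sige,
        "anomalous_floor": min_sige < CAP_BOUNDARIES[0],
    }
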
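"""Decision-table evaluation and the clinical scores the workflow consults.

The workflow's business-rule tasks delegate here: a decision table maps
typed inputs to outputs under a hit policy (``UNIQUE``: exactly one rule may
match; ``FIRST``: the first matching rule in document order wins).

Alongside table evaluation, this module implements the score calculators
used during the primary survey:

* **Glasgow Coma Scale** — eye (1-4) + verbal (1-5) + motor (1-6), range 3-15.
* **Injury Severity Score** — sum of squares of the three highest worst-region
  AIS severities over six body regions; any AIS 6 sets the score to 75.
* **Hemorrhagic shock class I-IV** — an ATLS-style staging over heart rate,
  systolic blood pressure, respiratory rate, mental status and estimated
  blood-loss fraction.  Each input is banded individually and the overall
  class is the worst (maximum) band, so worsening any input can never lower
  the class; band boundaries are assigned to the higher class.
* **Tranexamic acid indication** — give 1000 mg when the patient is actively
  bleeding or in shock class II or worse, within 3 h of injury.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Mapping

from .errors import DecisionEvaluationError, TypeMismatchError
from .model_io import DecisionModel

BODY_REGIONS = (
    "head_neck",
    "face",
    "chest",
    "abdomen",
    "extremities_pelvis",
    "external",
)

MENTAL_STATES = ("alert", "anxious", "confused", "lethargic", "unresponsive")


# ---------------------------------------------------------------------------
# Decision-table evaluation


@dataclass(frozen=True)
class EvaluationResult:
    outputs: dict
    rule_index: int  # 0-based index of the matched rule, for audit logging


def _check_input_type(name: str, value, value_type: str):
    if value_type == "number":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeMismatchError(f"input {name!r} must be a number, got {value!r}")
    elif value_type == "boolean":
        if not isinstance(value, bool):
            raise TypeMismatchError(f"input {name!r} must be a boolean, got {value!r}")
    elif value_type == "string":
        if not isinstance(value, str):
            raise TypeMismatchError(f"input {name!r} must be a string, got {value!r}")


def evaluate_decision(model: DecisionModel, inputs: Mapping) -> EvaluationResult:
    """Evaluate a decision table against a complete, typed input map.

    Returns the matched rule's outputs together with its index so that the
    caller (the engine's business-rule task) can audit-log the decision.
    Raises :class:`DecisionEvaluationError` on hit-policy violations.
    """
    values = []
    for inp in model.inputs:
        if inp.name not in inputs:
            raise TypeMismatchError(
                f"decision {model.decision_id!r} needs input {inp.name!r}"
            )
        value = inputs[inp.name]
        _check_input_type(inp.name, value, inp.value_type)
        if inp.allowed_values and value not in inp.allowed_values:
            raise TypeMismatchError(
                f"input {inp.name!r} value {value!r} outside allowed values"
            )
        values.append(value)

    matches = [
        i
        for i, rule in enumerate(model.rules)
        if all(cell.matches(v) for cell, v in zip(rule.cells, values))
    ]
    if not matches:
        raise DecisionEvaluationError(
            f"decision {model.decision_id!r}: no rule matches {dict(inputs)!r}"
        )
    if model.hit_policy == "UNIQUE" and len(matches) > 1:
        raise DecisionEvaluationError(
            f"decision {model.decision_id!r}: rules {matches} all match under UNIQUE"
        )
    idx = matches[0]
    rule = model.rules[idx]
    outputs = {out.name: value for out, value in zip(model.outputs, rule.outputs)}
    return EvaluationResult(outputs=outputs, rule_index=idx)


# ---------------------------------------------------------------------------
# Clinical scores


@dataclass(frozen=True)
class GcsComponents:
    eye: int
    verbal: int
    motor: int

    def __post_init__(self):
        if not (1 <= self.eye <= 4 and isinstance(self.eye, int)):
            raise ValueError(f"eye response must be 1-4, got {self.eye}")
        if not (1 <= self.verbal <= 5 and isinstance(self.verbal, int)):
            raise ValueError(f"verbal response must be 1-5, got {self.verbal}")
        if not (1 <= self.motor <= 6 and isinstance(self.motor, int)):
            raise ValueError(f"motor response must be 1-6, got {self.motor}")


def glasgow_coma_scale(c: GcsComponents) -> int:
    """Total GCS: eye + verbal + motor, range 3 (deep coma) to 15 (alert)."""
    return c.eye + c.verbal + c.motor


def injury_severity_score(ais: Mapping[str, int]) -> int:
    """Injury Severity Score from worst AIS severity per body region.

    Any region coded AIS 6 (unsurvivable) yields the maximum of 75; otherwise
    the score is the sum of squares of the three highest per-region values.
    An empty map scores 0.
    """
    for region, value in ais.items():
        if region not in BODY_REGIONS:
            raise ValueError(f"unknown body region {region!r}")
        if isinstance(value, bool) or not isinstance(value, int) or not 0 <= value <= 6:
            raise ValueError(f"AIS severity for {region!r} must be an integer 0-6")
    if any(v == 6 for v in ais.values()):
        return 75
    worst = sorted(ais.values(), reverse=True)[:3]
    return sum(v * v for v in worst)


@dataclass(frozen=True)
class VitalSigns:
    heart_rate: float
    systolic_bp: float
    resp_rate: float
    spo2: float
    mental_status: str

    def __post_init__(self):
        for label, v in (
            ("heart_rate", self.heart_rate),
            ("systolic_bp", self.systolic_bp),
            ("resp_rate", self.resp_rate),
            ("spo2", self.spo2),
        ):
            if v < 0:
                raise ValueError(f"{label} must be nonnegative")
        if self.spo2 > 100:
            raise ValueError("spo2 cannot exceed 100%")
        if self.mental_status not in MENTAL_STATES:
            raise ValueError(f"unknown mental status {self.mental_status!r}")


class ShockClass(IntEnum):
    I = 1
    II = 2
    III = 3
    IV = 4

    def __str__(self):
        return self.name


# Per-input band thresholds; each maps its value to the worst class it alone
# would justify.  Boundaries belong to the higher (worse) class.
def _hr_class(hr: float) -> int:
    if hr >= 140:
        return 4
    if hr >= 120:
        return 3
    if hr >= 100:
        return 2
    return 1


def _sbp_class(sbp: float) -> int:
    if sbp < 70:
        return 4
    if sbp <= 90:
        return 3
    if sbp <= 100:
        return 2
    return 1


def _rr_class(rr: float) -> int:
    if rr >= 35:
        return 4
    if rr >= 30:
        return 3
    if rr >= 20:
        return 2
    return 1


# Lethargy is banded as class III rather than IV so that depressed
# consciousness of neurological origin (severe TBI) does not by itself force
# the worst hemorrhage class; only unresponsiveness does.
_MENTAL_CLASS = {"alert": 1, "anxious": 2, "confused": 3, "lethargic": 3, "unresponsive": 4}


def _loss_class(fraction: float) -> int:
    if fraction >= 0.40:
        return 4
    if fraction >= 0.30:
        return 3
    if fraction >= 0.15:
        return 2
    return 1


def shock_class(v: VitalSigns, est_blood_loss_fraction: float) -> ShockClass:
    """ATLS-style hemorrhagic shock class I-IV (worst single-input band)."""
    if not 0 <= est_blood_loss_fraction <= 1:
        raise ValueError("blood-loss fraction must be in [0, 1]")
    worst = max(
        _hr_class(v.heart_rate),
        _sbp_class(v.systolic_bp),
        _rr_class(v.resp_rate),
        _MENTAL_CLASS[v.mental_status],
        _loss_class(est_blood_loss_fraction),
    )
    return ShockClass(worst)


TXA_DOSE_MG = 1000.0
TXA_WINDOW_MIN = 180.0


def txa_indicated(
    shock: ShockClass, actively_bleeding: bool, minutes_since_injury: float
) -> tuple[bool, float]:
    """Tranexamic-acid indication per the guideline rule encoded here.

    Indicated when the patient is actively bleeding or in shock class II or
    worse, provided less than 3 h have elapsed since injury; the loading dose
    is 1000 mg.
    """
    if minutes_since_injury < 0:
        raise ValueError("minutes_since_injury must be nonnegative")
    indicated = (actively_bleeding or shock >= ShockClass.II) and (
        minutes_since_injury < TXA_WINDOW_MIN
    )
    return indicated, TXA_DOSE_MG if indicated else 0.0
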
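"""CHA2DS2-VASc and HAS-BLED score calculators.

Standard clinical risk scores consumed by the rule engine as numeric
inputs: CHA2DS2-VASc estimates stroke risk in atrial fibrillation,
HAS-BLED estimates bleeding risk under anticoagulation.  Point values
follow the universally standardized definitions of each score (external
clinical knowledge, not specific to any one knowledge base).

The PROFUND index and the Pfeiffer questionnaire are *not* computed
here: their item-level definitions live in their own instruments, and
the engine treats them as opaque numeric observations.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .patient import Sex

__all__ = ["Cha2ds2VascComponents", "HasBledComponents", "cha2ds2vasc", "has_bled"]


class Cha2ds2VascComponents(BaseModel):
    """Inputs to CHA2DS2-VASc: Congestive heart failure, Hypertension,
    Age (>=75: 2 points; 65-74: 1), Diabetes, Stroke/TIA (2 points),
    Vascular disease, Sex category (female: 1)."""

    model_config = ConfigDict(frozen=True)

    congestive_heart_failure: bool = False
    hypertension: bool = False
    diabetes: bool = False
    stroke_or_tia_history: bool = False
    vascular_disease: bool = False
    age: int = Field(ge=0)
    sex: Sex


def cha2ds2vasc(c: Cha2ds2VascComponents) -> int:
    """CHA2DS2-VASc score, range 0-9."""
    score = 0
    score += c.congestive_heart_failure
    score += c.hypertension
    if c.age >= 75:
        score += 2
    elif c.age >= 65:
        score += 1
    score += c.diabetes
    score += 2 * c.stroke_or_tia_history
    score += c.vascular_disease
    score += c.sex is Sex.FEMALE
    return score


class HasBledComponents(BaseModel):
    """Inputs to HAS-BLED: Hypertension (uncontrolled), Abnormal renal
    and abnormal liver function (1 point each), Stroke, Bleeding history
    or predisposition, Labile INR, Elderly (age > 65), Drugs predisposing
    to bleeding and alcohol excess (1 point each)."""

    model_config = ConfigDict(frozen=True)

    hypertension_uncontrolled: bool = False
    abnormal_renal: bool = False
    abnormal_liver: bool = False
    stroke_history: bool = False
    bleeding_history: bool = False
    labile_inr: bool = False
    elderly: bool = False
    drugs_predisposing: bool = False
    alcohol_excess: bool = False


def has_bled(c: HasBledComponents) -> int:
    """HAS-BLED score, range 0-9: one point per positive item."""
    return sum(
        (
            c.hypertension_uncontrolled,
            c.abnormal_renal,
            c.abnormal_liver,
            c.stroke_history,
            c.bleeding_history,
            c.labile_inr,
            c.elderly,
            c.drugs_predisposing,
            c.alcohol_excess,
        )
    )
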
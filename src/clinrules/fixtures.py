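"""Packaged reference knowledge base, worked-example patient, generator.

The reference KB covers the atrial-fibrillation / oral-anticoagulation
scenario: every rule whose logic the knowledge sources print — nine
case rules, the ticlopidine mini-rule, the mitral-stenosis/mechanical-
valve super-rule blocking new oral anticoagulants, and the NIHSS
super-rule — together with the full concept and drug-class hierarchy
tables they need.  The deployed system it models contained further
rules whose logic is not public; those are intentionally not invented,
though the KB format supports authoring them.

``patient_zero`` is the retrospective validation case (male, 70 years,
nine chronic pathologies, fourteen prescribed drugs) under the closed
record policy: the case transcription is the patient's complete record.

:func:`generate_patients` draws seeded synthetic records for testing at
scale, with coherent risk scores computed from the sampled morbidity
profile via :mod:`clinrules.scores`.
"""

from __future__ import annotations

import json
import random
from importlib import resources
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from .knowledge import KnowledgeBase, load_kb
from .patient import PatientRecord, RecordPolicy, Sex, load_patient
from .scores import Cha2ds2VascComponents, HasBledComponents, cha2ds2vasc, has_bled

__all__ = [
    "reference_kb",
    "patient_zero",
    "patient_zero_bundle",
    "GeneratorParams",
    "default_prevalence",
    "generate_patients",
]


def _data(name: str):
    return resources.files("clinrules").joinpath("data").joinpath(name)


def reference_kb() -> KnowledgeBase:
    """Load the packaged reference knowledge base (12 rules)."""
    return load_kb(_data("reference_kb.yaml").read_text())


def patient_zero() -> PatientRecord:
    """Load the packaged worked-example patient record."""
    return load_patient(_data("patient_zero.yaml").read_text())


def patient_zero_bundle() -> dict:
    """The worked-example patient as a hand-built FHIR R4 Bundle."""
    return json.loads(_data("patient_zero_fhir.json").read_text())


#: attribute prevalences for a cohort of older multimorbid patients on
#: oral anticoagulation — typical outpatient figures for this population
_DEFAULT_PREVALENCE: dict[str, float] = {
    "atrial_fibrillation": 0.85,
    "arterial_hypertension": 0.75,
    "dyslipidemia": 0.55,
    "diabetes_mellitus_2": 0.35,
    "obesity": 0.35,
    "copd": 0.25,
    "asthma": 0.10,
    "prostatic_adenocarcinoma": 0.05,
    "mitral_stenosis": 0.05,
    "mechanical_heart_valve": 0.03,
    "stent_implanted": 0.10,
    "stent_thrombosis": 0.02,
    "acenocoumarol": 0.45,
    "aldocumar": 0.15,
    "apixaban": 0.10,
    "rivaroxaban": 0.10,
    "dabigatran": 0.05,
    "edoxaban": 0.05,
    "acetylsalicylic_acid": 0.30,
    "clopidogrel": 0.10,
    "ticlopidine": 0.02,
    "atorvastatin": 0.50,
    "omeprazole": 0.55,
    "paracetamol": 0.50,
    "metformin": 0.30,
    "irbesartan": 0.20,
    "hydrochlorothiazide": 0.25,
    "amlodipine": 0.30,
}


def default_prevalence() -> dict[str, float]:
    return dict(_DEFAULT_PREVALENCE)


class GeneratorParams(BaseModel):
    """Sampling parameters for the synthetic patient generator.

    ``prevalence`` maps boolean concept ids to presence probabilities;
    ``missingness`` is the probability that a present attribute is
    omitted from the record (undocumented, hence UNKNOWN under the open
    policy); ages are drawn from a clipped normal distribution.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    n_patients: int = Field(gt=0)
    prevalence: dict[str, float] = Field(default_factory=default_prevalence)
    missingness: float = Field(default=0.0, ge=0.0, le=1.0)
    age_mean: float = 78.0
    age_sd: float = Field(default=8.0, ge=0.0)
    age_min: int = 40
    age_max: int = 100
    female_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    record_policy: RecordPolicy = RecordPolicy.OPEN

    def validate_against(self, kb: KnowledgeBase) -> None:
        for cid, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cid!r} outside [0, 1]")
            if not kb.has_concept(cid):
                raise KeyError(f"prevalence references unknown concept {cid!r}")


def _sample_one(rng: random.Random, params: GeneratorParams, kb: KnowledgeBase, i: int) -> PatientRecord:
    age = int(min(max(rng.gauss(params.age_mean, params.age_sd), params.age_min), params.age_max))
    sex = Sex.FEMALE if rng.random() < params.female_fraction else Sex.MALE

    conditions: list[str] = []
    medications: list[str] = []
    for cid in sorted(params.prevalence):
        if rng.random() >= params.prevalence[cid]:
            continue
        if rng.random() < params.missingness:
            continue  # present but undocumented
        if kb.concept(cid).section == "treatment":
            medications.append(cid)
        else:
            conditions.append(cid)

    stroke_history = rng.random() < 0.10
    chads = cha2ds2vasc(
        Cha2ds2VascComponents(
            congestive_heart_failure=rng.random() < 0.20,
            hypertension="arterial_hypertension" in conditions,
            diabetes="diabetes_mellitus_2" in conditions,
            stroke_or_tia_history=stroke_history,
            vascular_disease="stent_implanted" in conditions,
            age=age,
            sex=sex,
        )
    )
    bled = has_bled(
        HasBledComponents(
            hypertension_uncontrolled="arterial_hypertension" in conditions and rng.random() < 0.3,
            abnormal_renal=rng.random() < 0.15,
            abnormal_liver=rng.random() < 0.05,
            stroke_history=stroke_history,
            bleeding_history=rng.random() < 0.10,
            labile_inr=rng.random() < 0.20,
            elderly=age > 65,
            drugs_predisposing=any(
                m in medications for m in ("acetylsalicylic_acid", "clopidogrel", "ticlopidine")
            ),
            alcohol_excess=rng.random() < 0.05,
        )
    )

    observations: dict[str, Union[float, int, str]] = {}
    if rng.random() >= params.missingness:
        observations["cha2ds2_vasc"] = chads
    if rng.random() >= params.missingness:
        observations["has_bled"] = bled

    return PatientRecord(
        patient_id=f"synthetic-{i:04d}",
        sex=sex,
        age=age,
        conditions=tuple(conditions),
        medications=tuple(medications),
        observations=observations,
        record_policy=params.record_policy,
    )


def generate_patients(
    params: GeneratorParams, kb: Optional[KnowledgeBase] = None
) -> list[PatientRecord]:
    """Draw ``params.n_patients`` seeded synthetic patient records.

    The full output stream is fixed by ``params.seed``; concepts are
    sampled in sorted-id order from a single pseudo-random stream.
    """
    if kb is None:
        kb = reference_kb()
    params.validate_against(kb)
    rng = random.Random(params.seed)
    return [_sample_one(rng, params, kb, i) for i in range(params.n_patients)]
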
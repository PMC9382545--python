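"""Patient records, three-valued fact bases, FHIR ingestion, eligibility.

A :class:`PatientRecord` lists what is *asserted* about a patient:
diagnosed conditions, prescribed medications, and observed values
(scores, measurements).  :func:`build_facts` turns it into a
:class:`FactBase` against a knowledge base, applying the drug-class
hierarchy closure (a prescribed brand asserts every ancestor class) and
the record policy:

* **open** (default) — an unasserted boolean concept is UNKNOWN;
  absence of evidence is not evidence of absence.
* **closed** — an unasserted boolean concept is FALSE; appropriate when
  the record is known to be complete.

Numeric and categorical concepts without an observation stay UNKNOWN
under either policy.
"""

from __future__ import annotations

import datetime
import enum
import io
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .knowledge import KnowledgeBase, ValueKind
from .logic import TruthValue

__all__ = [
    "Sex",
    "RecordPolicy",
    "Provenance",
    "PatientRecord",
    "FactBase",
    "UnknownConceptError",
    "FhirIngestError",
    "SkippedEntry",
    "FhirIngestResult",
    "EligibilityCriteria",
    "CriterionResult",
    "EligibilityResult",
    "build_facts",
    "ingest_fhir_bundle",
    "screen_eligibility",
    "load_patient",
    "save_patient",
]

#: concept ids the engine recognises when present in a knowledge base
AGE_CONCEPT = "age"
SEX_CONCEPT = "sex"
MEDICATION_COUNT_CONCEPT = "medication_count"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class RecordPolicy(str, enum.Enum):
    CLOSED = "closed"
    OPEN = "open"


class Provenance(str, enum.Enum):
    ASSERTED = "asserted"
    DERIVED_FROM_HIERARCHY = "derived_from_hierarchy"
    DEFAULT_POLICY = "default_policy"


class UnknownConceptError(KeyError):
    """A record references a concept id the knowledge base lacks."""


class PatientRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    sex: Sex = Sex.UNKNOWN
    age: int = Field(ge=0)
    conditions: tuple[str, ...] = ()
    medications: tuple[str, ...] = ()
    observations: dict[str, Union[float, int, str]] = {}
    record_policy: RecordPolicy = RecordPolicy.OPEN


FactValue = Union[TruthValue, float, int, str]


class FactBase(BaseModel):
    """Per-concept assignments for one patient.

    Boolean concepts map to a :class:`TruthValue`; number/category
    concepts map to their observed value, or ``TruthValue.UNKNOWN`` when
    unobserved.  Every concept of the KB the facts were built against
    has an entry.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    assignments: dict[str, FactValue]
    provenance: dict[str, Provenance]

    def truth(self, concept_id: str) -> TruthValue:
        """Truth value of a boolean concept."""
        v = self.assignments[concept_id]
        if not isinstance(v, TruthValue):
            raise TypeError(f"{concept_id!r} holds a value, not a truth value")
        return v

    def value(self, concept_id: str) -> FactValue:
        return self.assignments[concept_id]

    def is_unknown(self, concept_id: str) -> bool:
        return self.assignments[concept_id] is TruthValue.UNKNOWN


def build_facts(patient: PatientRecord, kb: KnowledgeBase) -> FactBase:
    """Materialize a three-valued fact base for ``patient`` against ``kb``.

    Asserted conditions and medications become TRUE, their hierarchy
    ancestors become TRUE with ``derived_from_hierarchy`` provenance,
    observations are copied, and remaining boolean concepts take the
    record-policy default.  Age, sex and the distinct-medication count
    are published under the ``age`` / ``sex`` / ``medication_count``
    concept ids when the KB declares them.
    """
    concept_ids = {c.id for c in kb.concepts}
    for cid in (*patient.conditions, *patient.medications, *patient.observations):
        if cid not in concept_ids:
            raise UnknownConceptError(f"record references unknown concept {cid!r}")

    default = TruthValue.FALSE if patient.record_policy is RecordPolicy.CLOSED else TruthValue.UNKNOWN
    assignments: dict[str, FactValue] = {}
    provenance: dict[str, Provenance] = {}
    for c in kb.concepts:
        assignments[c.id] = default if c.value_kind is ValueKind.BOOLEAN else TruthValue.UNKNOWN
        provenance[c.id] = Provenance.DEFAULT_POLICY

    asserted = (*patient.conditions, *patient.medications)
    for cid in asserted:
        assignments[cid] = TruthValue.TRUE
        provenance[cid] = Provenance.ASSERTED
    for cid in asserted:
        for ancestor in kb.ancestors(cid):
            if provenance[ancestor] is not Provenance.ASSERTED:
                assignments[ancestor] = TruthValue.TRUE
                provenance[ancestor] = Provenance.DERIVED_FROM_HIERARCHY

    for cid, value in patient.observations.items():
        assignments[cid] = value
        provenance[cid] = Provenance.ASSERTED

    if AGE_CONCEPT in concept_ids:
        assignments[AGE_CONCEPT] = patient.age
        provenance[AGE_CONCEPT] = Provenance.ASSERTED
    if SEX_CONCEPT in concept_ids and patient.sex is not Sex.UNKNOWN:
        assignments[SEX_CONCEPT] = patient.sex.value
        provenance[SEX_CONCEPT] = Provenance.ASSERTED
    if MEDICATION_COUNT_CONCEPT in concept_ids:
        assignments[MEDICATION_COUNT_CONCEPT] = len(set(patient.medications))
        provenance[MEDICATION_COUNT_CONCEPT] = Provenance.ASSERTED

    return FactBase(assignments=assignments, provenance=provenance)


# ---------------------------------------------------------------------------
# FHIR R4 bundle ingestion

class FhirIngestError(ValueError):
    """The bundle is malformed or lacks exactly one Patient resource."""


class SkippedEntry(BaseModel):
    resource_type: str
    reason: str
    codings: tuple[tuple[str, str], ...] = ()


class FhirIngestResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    record: PatientRecord
    skipped: tuple[SkippedEntry, ...] = ()


def _codings(codeable: Optional[dict]) -> list[tuple[str, str]]:
    if not codeable:
        return []
    return [
        (c.get("system", ""), c.get("code", ""))
        for c in codeable.get("coding", [])
        if c.get("code")
    ]


def _age_at(birth_date: str, reference: datetime.date) -> int:
    born = datetime.date.fromisoformat(birth_date)
    years = reference.year - born.year
    if (reference.month, reference.day) < (born.month, born.day):
        years -= 1
    return max(years, 0)


def ingest_fhir_bundle(
    bundle: Union[dict, str, Path, io.TextIOBase],
    kb: KnowledgeBase,
    reference_date: datetime.date,
    record_policy: RecordPolicy = RecordPolicy.OPEN,
) -> FhirIngestResult:
    """Convert a FHIR R4 Bundle into a native patient record.

    Conditions, medications (MedicationStatement / MedicationRequest
    with active status) and Observations are matched against concept
    FHIR annotations by exact (resource type, code system, code)
    equality; entries with no matching concept are collected in the
    skipped-entries report rather than raised.  Age is computed from the
    Patient resource's birthDate against ``reference_date``.
    """
    if isinstance(bundle, Path):
        doc = json.loads(bundle.read_text())
    elif isinstance(bundle, str):
        p = Path(bundle)
        doc = json.loads(p.read_text() if p.suffix == ".json" and p.exists() else bundle)
    elif hasattr(bundle, "read"):
        doc = json.load(bundle)
    else:
        doc = bundle
    if not isinstance(doc, dict) or doc.get("resourceType") != "Bundle":
        raise FhirIngestError("document is not a FHIR Bundle")

    index: dict[tuple[str, str, str], str] = {}
    for c in kb.concepts:
        ann = c.fhir_annotation
        if ann is not None:
            index[(ann.resource_type, ann.code_system, ann.code)] = c.id

    resources = [
        e.get("resource", {})
        for e in doc.get("entry", [])
        if isinstance(e, dict) and isinstance(e.get("resource"), dict)
    ]
    patients = [r for r in resources if r.get("resourceType") == "Patient"]
    if len(patients) != 1:
        raise FhirIngestError(f"bundle must contain exactly one Patient resource, found {len(patients)}")
    p = patients[0]
    if "birthDate" not in p:
        raise FhirIngestError("Patient resource lacks birthDate")

    sex = {"male": Sex.MALE, "female": Sex.FEMALE}.get(p.get("gender", ""), Sex.UNKNOWN)
    conditions: list[str] = []
    medications: list[str] = []
    observations: dict[str, Union[float, int, str]] = {}
    skipped: list[SkippedEntry] = []

    def match(rtype: str, codings: list[tuple[str, str]]) -> Optional[str]:
        for system, code in codings:
            cid = index.get((rtype, system, code))
            if cid is not None:
                return cid
        return None

    for r in resources:
        rtype = r.get("resourceType", "")
        if rtype == "Condition":
            codings = _codings(r.get("code"))
            cid = match("Condition", codings)
            if cid is None:
                skipped.append(SkippedEntry(resource_type=rtype, reason="no matching concept", codings=tuple(codings)))
            elif cid not in conditions:
                conditions.append(cid)
        elif rtype in ("MedicationStatement", "MedicationRequest"):
            if r.get("status") not in ("active", None):
                continue
            codings = _codings(r.get("medicationCodeableConcept"))
            cid = match("MedicationStatement", codings) or match("MedicationRequest", codings)
            if cid is None:
                skipped.append(SkippedEntry(resource_type=rtype, reason="no matching concept", codings=tuple(codings)))
            elif cid not in medications:
                medications.append(cid)
        elif rtype == "Observation":
            codings = _codings(r.get("code"))
            cid = match("Observation", codings)
            if cid is None:
                skipped.append(SkippedEntry(resource_type=rtype, reason="no matching concept", codings=tuple(codings)))
                continue
            if "valueQuantity" in r:
                observations[cid] = r["valueQuantity"].get("value")
            elif "valueInteger" in r:
                observations[cid] = r["valueInteger"]
            elif "valueString" in r:
                observations[cid] = r["valueString"]
            elif "valueCodeableConcept" in r:
                vc = _codings(r["valueCodeableConcept"])
                observations[cid] = vc[0][1] if vc else ""
            else:
                skipped.append(SkippedEntry(resource_type=rtype, reason="no usable value", codings=tuple(codings)))

    record = PatientRecord(
        patient_id=p.get("id", "patient"),
        sex=sex,
        age=_age_at(p["birthDate"], reference_date),
        conditions=tuple(conditions),
        medications=tuple(medications),
        observations=observations,
        record_policy=record_policy,
    )
    return FhirIngestResult(record=record, skipped=tuple(skipped))


# ---------------------------------------------------------------------------
# Study eligibility screening

class EligibilityCriteria(BaseModel):
    """Inclusion/exclusion thresholds for complex-chronic-patient studies.

    Defaults encode: age >= 65, polypharmacy (>= 5 distinct drugs),
    multimorbidity (>= 2 chronic conditions), atrial fibrillation
    present, at least one oral anticoagulant prescribed, and not at end
    of life (short-term prognosis).
    """

    model_config = ConfigDict(frozen=True)

    min_age: int = 65
    min_medications: int = 5
    min_chronic_conditions: int = 2
    required_condition: str = "atrial_fibrillation"
    required_medication_class: str = "oral_anticoagulant"
    exclusion_flag: str = "end_of_life"


class CriterionResult(BaseModel):
    name: str
    status: str  # "pass" | "fail" | "unknown"
    measured: Union[int, bool, str, None] = None


class EligibilityResult(BaseModel):
    eligible: bool
    criterion_results: tuple[CriterionResult, ...]


def screen_eligibility(
    patient: PatientRecord,
    kb: KnowledgeBase,
    criteria: EligibilityCriteria = EligibilityCriteria(),
) -> EligibilityResult:
    """Evaluate each inclusion criterion and the exclusion criterion.

    A criterion that cannot be decided (e.g. the KB lacks the required
    concept) reports ``unknown`` and makes the patient ineligible.
    """
    results: list[CriterionResult] = []

    def add(name: str, ok: Optional[bool], measured) -> None:
        status = "unknown" if ok is None else ("pass" if ok else "fail")
        results.append(CriterionResult(name=name, status=status, measured=measured))

    add("age", patient.age >= criteria.min_age, patient.age)

    n_meds = len(set(patient.medications))
    add("polypharmacy", n_meds >= criteria.min_medications, n_meds)

    chronic_ids = {c.id for c in kb.concepts if c.chronic}
    n_chronic = len(set(patient.conditions) & chronic_ids)
    add("multimorbidity", n_chronic >= criteria.min_chronic_conditions, n_chronic)

    if kb.has_concept(criteria.required_condition):
        add(
            "required_condition",
            criteria.required_condition in patient.conditions,
            criteria.required_condition,
        )
    else:
        add("required_condition", None, criteria.required_condition)

    if kb.has_concept(criteria.required_medication_class):
        has_class = any(
            m == criteria.required_medication_class
            or criteria.required_medication_class in kb.ancestors(m)
            for m in patient.medications
        )
        add("required_medication_class", has_class, criteria.required_medication_class)
    else:
        add("required_medication_class", None, criteria.required_medication_class)

    flagged = criteria.exclusion_flag in patient.conditions
    add("not_end_of_life", not flagged, flagged)

    eligible = all(r.status == "pass" for r in results)
    return EligibilityResult(eligible=eligible, criterion_results=tuple(results))


# ---------------------------------------------------------------------------
# Native patient file format (YAML)

def save_patient(patient: PatientRecord) -> str:
    doc = {
        "patient_id": patient.patient_id,
        "sex": patient.sex.value,
        "age": patient.age,
        "conditions": list(patient.conditions),
        "medications": list(patient.medications),
        "observations": dict(patient.observations),
        "record_policy": patient.record_policy.value,
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def load_patient(source: Union[str, Path, io.TextIOBase]) -> PatientRecord:
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml")):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    doc = yaml.safe_load(text) or {}
    return PatientRecord(
        patient_id=str(doc.get("patient_id", "patient")),
        sex=Sex(doc.get("sex", "unknown")),
        age=int(doc["age"]),
        conditions=tuple(doc.get("conditions") or ()),
        medications=tuple(doc.get("medications") or ()),
        observations=dict(doc.get("observations") or {}),
        record_policy=RecordPolicy(doc.get("record_policy", "open")),
    )
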
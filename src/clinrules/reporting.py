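"""Professional-facing report rendering and feedback capture.

The report mirrors the informational content a prescriber needs to act
on the engine's output: the patient header, prescribing advice (the
prescribe and monitor categories together), deprescription advice, and
the recommendations that could not be evaluated for lack of
information — each of the latter with the missing items whose
completion could actually change the decision.  Every recommendation
block lists the fulfilled premises with their observed values and the
evidence provenance (source document, section, page, evidence level),
so the professional can audit why the rule fired.

Output is deterministic plain text: identical inputs render
byte-identical documents.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .engine import EvaluationResult, Recommendation
from .knowledge import Comparator, KnowledgeBase
from .patient import PatientRecord

__all__ = ["FeedbackEntry", "FeedbackError", "render_report", "record_feedback"]

_CMP_TEXT = {
    Comparator.IS_TRUE: "is present",
    Comparator.IS_FALSE: "is absent",
    Comparator.EQ: "=",
    Comparator.NE: "≠",
    Comparator.LT: "<",
    Comparator.LE: "≤",
    Comparator.GT: ">",
    Comparator.GE: "≥",
    Comparator.BETWEEN: "between",
}


def _label(kb: KnowledgeBase, concept_id: str) -> str:
    return kb.concept(concept_id).label if kb.has_concept(concept_id) else concept_id


def _premise_line(kb: KnowledgeBase, p) -> str:
    label = _label(kb, p.concept_id)
    if p.comparator in (Comparator.IS_TRUE, Comparator.IS_FALSE):
        return f"{label} {_CMP_TEXT[p.comparator]}"
    if p.comparator is Comparator.BETWEEN:
        low, high = p.value
        cond = f"{label} between {low} and {high}"
    else:
        cond = f"{label} {_CMP_TEXT[p.comparator]} {p.value}"
    return f"{cond} (observed: {p.observed})"


def _recommendation_block(kb: KnowledgeBase, rec: Recommendation) -> list[str]:
    ev = rec.evidence
    lines = [f"* [{rec.rule_id}] {rec.statement.text}"]
    lines.append("  Fulfilled premises:")
    for p in rec.justification:
        lines.append(f"    - {_premise_line(kb, p)}")
    lines.append(f"  Evidence: {ev.source_document}")
    detail = [
        f"{name}: {value}"
        for name, value in (
            ("section", ev.section),
            ("page", ev.page),
            ("level of evidence", ev.evidence_level),
        )
        if value is not None
    ]
    if detail:
        lines.append("    " + "; ".join(detail))
    return lines


def render_report(
    result: EvaluationResult, patient: PatientRecord, kb: KnowledgeBase
) -> str:
    """Render an evaluation result as a deterministic plain-text report."""
    lines: list[str] = []
    lines.append("CLINICAL DECISION SUPPORT REPORT")
    lines.append("=" * 32)
    lines.append(f"Patient: {patient.patient_id}")
    lines.append(f"Sex: {patient.sex.value}    Age: {patient.age} years")
    lines.append(f"Record policy: {patient.record_policy.value}")
    lines.append("")

    lines.append("RECOMMENDATIONS ON PRESCRIBING")
    lines.append("-" * 30)
    if result.prescribe_group:
        for rec in result.prescribe_group:
            lines.extend(_recommendation_block(kb, rec))
    else:
        lines.append("(none)")
    lines.append("")

    lines.append("RECOMMENDATIONS ON DEPRESCRIPTION")
    lines.append("-" * 33)
    if result.deprescribe_group:
        for rec in result.deprescribe_group:
            lines.extend(_recommendation_block(kb, rec))
    else:
        lines.append("(none)")
    lines.append("")

    lines.append("NOT EVALUATED — INSUFFICIENT INFORMATION")
    lines.append("-" * 40)
    if result.not_evaluable:
        for cf in result.not_evaluable:
            lines.append(f"* [{cf.rule_id}] could not be evaluated.")
            if cf.decision_relevant_atoms:
                missing = ", ".join(_label(kb, a) for a in cf.decision_relevant_atoms)
                lines.append(f"  Completing these items could change the decision: {missing}")
            else:
                lines.append("  No missing item can change the decision.")
            lines.append(
                f"  If completed: rule could fire: {'yes' if cf.fire_possible else 'no'}; "
                f"would fire regardless: {'yes' if cf.fire_certain else 'no'}"
            )
    else:
        lines.append("(none)")
    lines.append("")
    return "\n".join(lines)


class FeedbackError(ValueError):
    """Invalid feedback: unknown rule or rejection without justification."""


class FeedbackEntry(BaseModel):
    """A professional's verdict on one displayed recommendation.

    Recommendations are advisory, never mandatory; a rejected one must
    carry the professional's justification, which is what lets actual
    practice feed back into the knowledge sources.
    """

    model_config = ConfigDict(frozen=True)

    rule_id: str
    accepted: bool
    justification_text: Optional[str] = None

    @model_validator(mode="after")
    def _justified_rejection(self) -> "FeedbackEntry":
        if not self.accepted and not self.justification_text:
            raise ValueError(
                f"rejection of {self.rule_id!r} requires justification_text"
            )
        return self


def record_feedback(
    entries: list[FeedbackEntry], result: EvaluationResult
) -> str:
    """Validate feedback against a result and render the append-only log.

    Returns a YAML document (a list of entries) suitable for appending
    to a feedback log file.  Raises :class:`FeedbackError` if an entry
    references a rule with no displayed recommendation or rejects one
    without justification.
    """
    known = {rec.rule_id for rec in result.recommendations}
    for entry in entries:
        if entry.rule_id not in known:
            raise FeedbackError(
                f"feedback references rule {entry.rule_id!r} with no displayed recommendation"
            )
        if not entry.accepted and not entry.justification_text:
            raise FeedbackError(
                f"rejection of {entry.rule_id!r} requires justification_text"
            )
    doc = [
        {
            "rule_id": e.rule_id,
            "accepted": e.accepted,
            **({"justification_text": e.justification_text} if e.justification_text else {}),
        }
        for e in entries
    ]
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
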
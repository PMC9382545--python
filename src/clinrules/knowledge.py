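"""Declarative knowledge base: concepts, premises, rules, statements.

The knowledge base is the computable form of prescription/deprescription
criteria extracted from clinical knowledge sources (practice guidelines,
STOPP/START-style catalogues, Delphi deprescription lists).  Its building
blocks:

* **clinical concept** — a named variable (a condition, a drug or drug
  class, a score) with a value kind (boolean / number / category) and
  optional FHIR and SNOMED CT terminology annotations;
* **premise** — a comparator condition over one concept's value;
* **mini-rule** — a single premise bound to a clinical statement;
* **super-rule** — several premises combined with and/or connectives
  bound to a clinical statement;
* **clinical statement** — the recommendation text shown to the
  professional, with its category and evidence provenance.

A drug-class hierarchy (e.g. brand -> active substance -> vitamin K
antagonist -> oral anticoagulant) lets rules written against classes
match records that list named products.

The persisted format is a YAML document; see ``docs/kb_format.md`` and
:func:`load_kb` / :func:`save_kb`.
"""

from __future__ import annotations

import enum
import io
import re
from pathlib import Path
from typing import Iterator, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "ValueKind",
    "Comparator",
    "Connective",
    "FhirAnnotation",
    "ClinicalConcept",
    "HierarchyLink",
    "Premise",
    "Node",
    "PremiseExpr",
    "StatementCategory",
    "EvidenceRef",
    "ClinicalStatement",
    "RuleKind",
    "Rule",
    "KnowledgeBase",
    "Issue",
    "KBError",
    "KBParseError",
    "KBValidationError",
    "load_kb",
    "save_kb",
    "validate_kb",
    "mapping_coverage",
    "kb_json_schema",
]

_SNOMED_RE = re.compile(r"^\d{6,18}$")


class KBError(Exception):
    """Base class for knowledge-base errors."""


class KBParseError(KBError):
    """The document does not conform to the KB schema."""

    def __init__(self, message: str, path: str = "$") -> None:
        self.path = path
        super().__init__(f"{path}: {message}")


class KBValidationError(KBError):
    """A structurally well-formed KB violates semantic invariants."""

    def __init__(self, issues: list["Issue"]) -> None:
        self.issues = issues
        lines = "; ".join(str(i) for i in issues)
        super().__init__(f"knowledge base invalid: {lines}")


class ValueKind(str, enum.Enum):
    BOOLEAN = "boolean"
    NUMBER = "number"
    CATEGORY = "category"


class Comparator(str, enum.Enum):
    IS_TRUE = "is_true"
    IS_FALSE = "is_false"
    EQ = "eq"
    NE = "ne"
    LT = "lt"
    LE = "le"
    GT = "gt"
    GE = "ge"
    BETWEEN = "between"


#: comparators admissible for each value kind
_KIND_COMPARATORS = {
    ValueKind.BOOLEAN: {Comparator.IS_TRUE, Comparator.IS_FALSE},
    ValueKind.NUMBER: {
        Comparator.EQ,
        Comparator.NE,
        Comparator.LT,
        Comparator.LE,
        Comparator.GT,
        Comparator.GE,
        Comparator.BETWEEN,
    },
    ValueKind.CATEGORY: {Comparator.EQ, Comparator.NE},
}


class Connective(str, enum.Enum):
    AND = "and"
    OR = "or"


class FhirAnnotation(BaseModel):
    """FHIR R4 mapping of a concept: which resource carries it and under
    which (code system, code) pair it is coded."""

    model_config = ConfigDict(frozen=True)

    resource_type: str
    code_system: str
    code: str


class ClinicalConcept(BaseModel):
    """A named clinical variable that premises constrain.

    ``chronic`` flags condition concepts that count toward the
    multimorbidity criterion; ``section`` is input-grouping metadata
    (anamnesis / exploration / complementary_tests / treatment) for the
    data-collection form, with no effect on evaluation.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    label: str
    value_kind: ValueKind = ValueKind.BOOLEAN
    units: Optional[str] = None
    fhir_annotation: Optional[FhirAnnotation] = None
    snomed_annotation: Optional[str] = None
    chronic: bool = False
    section: Optional[str] = None


class HierarchyLink(BaseModel):
    """Is-a link from a specific concept to its class (drug -> drug class)."""

    model_config = ConfigDict(frozen=True)

    child_id: str
    parent_id: str


PremiseValue = Union[bool, int, float, str, tuple, list, None]


class Premise(BaseModel):
    """A comparator condition on one concept's value.

    ``value`` is unused for is_true/is_false, a scalar for the ordering
    and equality comparators, and a (low, high) pair for between.
    """

    model_config = ConfigDict(frozen=True)

    concept_id: str
    comparator: Comparator
    value: PremiseValue = None

    def key(self) -> tuple:
        """Identity of the premise as a counterfactual atom."""
        v = self.value
        if isinstance(v, list):
            v = tuple(v)
        return (self.concept_id, self.comparator, v)


class Node(BaseModel):
    """An n-ary and/or connective over two or more sub-expressions."""

    model_config = ConfigDict(frozen=True)

    op: Connective
    children: tuple["PremiseExpr", ...] = Field(min_length=2)


PremiseExpr = Union[Premise, Node]
Node.model_rebuild()


def iter_leaves(expr: PremiseExpr) -> Iterator[Premise]:
    """Yield every leaf premise of an expression, left to right."""
    if isinstance(expr, Premise):
        yield expr
    else:
        for child in expr.children:
            yield from iter_leaves(child)


class StatementCategory(str, enum.Enum):
    PRESCRIBE = "prescribe"
    DEPRESCRIBE = "deprescribe"
    #: surveillance advice; displayed under the prescribing group
    MONITOR = "monitor"


class EvidenceRef(BaseModel):
    """Provenance of a recommendation in its knowledge source."""

    model_config = ConfigDict(frozen=True)

    source_document: str
    section: Optional[str] = None
    page: Optional[str] = None
    evidence_level: Optional[str] = None


class ClinicalStatement(BaseModel):
    """The recommendation shown to the professional when a rule fires."""

    model_config = ConfigDict(frozen=True)

    text: str
    category: StatementCategory
    evidence: EvidenceRef


class RuleKind(str, enum.Enum):
    MINI = "mini"
    SUPER = "super"


class Rule(BaseModel):
    """A premise expression bound to a clinical statement.

    A mini-rule has a single leaf premise; a super-rule combines several
    premises with and/or connectives.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    kind: RuleKind
    expr: PremiseExpr
    statement: ClinicalStatement


class KnowledgeBase(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str = "knowledge-base"
    version: str = "0"
    concepts: tuple[ClinicalConcept, ...] = ()
    hierarchy: tuple[HierarchyLink, ...] = ()
    rules: tuple[Rule, ...] = ()

    def concept(self, concept_id: str) -> ClinicalConcept:
        for c in self.concepts:
            if c.id == concept_id:
                return c
        raise KeyError(f"unknown concept id: {concept_id!r}")

    def has_concept(self, concept_id: str) -> bool:
        return any(c.id == concept_id for c in self.concepts)

    def parents(self, concept_id: str) -> list[str]:
        return [l.parent_id for l in self.hierarchy if l.child_id == concept_id]

    def ancestors(self, concept_id: str) -> set[str]:
        """Transitive closure of is-a parents (excludes the concept itself)."""
        seen: set[str] = set()
        frontier = [concept_id]
        while frontier:
            current = frontier.pop()
            for parent in self.parents(current):
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen


class Issue(BaseModel):
    """One validation finding; issues are data, not exceptions."""

    severity: str  # "error" | "warning"
    location: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.location}: {self.message}"


def validate_kb(kb: KnowledgeBase) -> list[Issue]:
    """Check every semantic invariant; return an empty list iff all hold."""
    issues: list[Issue] = []

    def err(location: str, message: str) -> None:
        issues.append(Issue(severity="error", location=location, message=message))

    seen_concepts: set[str] = set()
    for c in kb.concepts:
        loc = f"concepts[{c.id}]"
        if c.id in seen_concepts:
            err(loc, "duplicate concept id")
        seen_concepts.add(c.id)
        if c.snomed_annotation is not None and not _SNOMED_RE.match(c.snomed_annotation):
            err(loc, f"snomed_annotation {c.snomed_annotation!r} is not a 6-18 digit numeral")
        if c.units is not None and c.value_kind is not ValueKind.NUMBER:
            err(loc, f"units given for {c.value_kind.value} concept")
        if not c.label:
            err(loc, "empty label")

    concept_ids = {c.id for c in kb.concepts}

    children: dict[str, list[str]] = {}
    for i, link in enumerate(kb.hierarchy):
        loc = f"hierarchy[{i}]"
        for ref in (link.child_id, link.parent_id):
            if ref not in concept_ids:
                err(loc, f"dangling concept reference {ref!r}")
        children.setdefault(link.child_id, []).append(link.parent_id)

    # cycle detection on the is-a graph (iterative DFS, three colours)
    colour: dict[str, int] = {}
    for start in children:
        if colour.get(start):
            continue
        stack: list[tuple[str, Iterator[str]]] = [(start, iter(children.get(start, ())))]
        colour[start] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                state = colour.get(nxt, 0)
                if state == 1:
                    err("hierarchy", f"cycle through {nxt!r}")
                elif state == 0:
                    colour[nxt] = 1
                    stack.append((nxt, iter(children.get(nxt, ()))))
                    advanced = True
                    break
            if not advanced:
                colour[node] = 2
                stack.pop()

    seen_rules: set[str] = set()
    for rule in kb.rules:
        loc = f"rules[{rule.id}]"
        if rule.id in seen_rules:
            err(loc, "duplicate rule id")
        seen_rules.add(rule.id)

        is_leaf = isinstance(rule.expr, Premise)
        if rule.kind is RuleKind.MINI and not is_leaf:
            err(loc, "mini-rule must have a single leaf premise")
        if rule.kind is RuleKind.SUPER and is_leaf:
            err(loc, "super-rule must have a connective expression")

        for leaf in iter_leaves(rule.expr):
            ploc = f"{loc}.expr({leaf.concept_id})"
            if leaf.concept_id not in concept_ids:
                err(ploc, f"dangling concept reference {leaf.concept_id!r}")
                continue
            kind = kb.concept(leaf.concept_id).value_kind
            if leaf.comparator not in _KIND_COMPARATORS[kind]:
                err(ploc, f"comparator {leaf.comparator.value} incompatible with {kind.value} concept")
            if leaf.comparator is Comparator.BETWEEN:
                v = leaf.value
                if not (isinstance(v, (list, tuple)) and len(v) == 2):
                    err(ploc, "between requires a (low, high) pair")
                elif v[0] > v[1]:
                    err(ploc, "between bounds out of order")
            elif leaf.comparator in (Comparator.IS_TRUE, Comparator.IS_FALSE):
                if leaf.value is not None:
                    err(ploc, f"{leaf.comparator.value} takes no value")
            elif leaf.value is None or isinstance(leaf.value, (list, tuple)):
                err(ploc, f"{leaf.comparator.value} requires a scalar value")

        if not rule.statement.text:
            err(loc, "empty statement text")
        if not rule.statement.evidence.source_document:
            err(loc, "empty evidence source_document")

    return issues


def mapping_coverage(kb: KnowledgeBase) -> Optional[tuple[float, float]]:
    """Fractions of concepts carrying FHIR and SNOMED CT annotations.

    Returns ``(fhir_fraction, snomed_fraction)``, or ``None`` for a KB
    with no concepts (coverage undefined).
    """
    n = len(kb.concepts)
    if n == 0:
        return None
    fhir = sum(1 for c in kb.concepts if c.fhir_annotation is not None)
    snomed = sum(1 for c in kb.concepts if c.snomed_annotation is not None)
    return fhir / n, snomed / n


# ---------------------------------------------------------------------------
# YAML dialect

def _expr_to_obj(expr: PremiseExpr) -> dict:
    if isinstance(expr, Premise):
        obj: dict = {"concept": expr.concept_id, "comparator": expr.comparator.value}
        if expr.value is not None:
            obj["value"] = list(expr.value) if isinstance(expr.value, tuple) else expr.value
        return obj
    key = "all_of" if expr.op is Connective.AND else "any_of"
    return {key: [_expr_to_obj(c) for c in expr.children]}


def _expr_from_obj(obj: object, path: str) -> PremiseExpr:
    if not isinstance(obj, dict):
        raise KBParseError("expression must be a mapping", path)
    if "all_of" in obj or "any_of" in obj:
        key = "all_of" if "all_of" in obj else "any_of"
        raw_children = obj[key]
        if not isinstance(raw_children, list) or len(raw_children) < 2:
            raise KBParseError(f"{key} requires a list of >=2 expressions", path)
        children = tuple(
            _expr_from_obj(c, f"{path}.{key}[{i}]") for i, c in enumerate(raw_children)
        )
        op = Connective.AND if key == "all_of" else Connective.OR
        return Node(op=op, children=children)
    try:
        value = obj.get("value")
        if isinstance(value, list):
            value = tuple(value)
        return Premise(
            concept_id=obj["concept"],
            comparator=Comparator(obj["comparator"]),
            value=value,
        )
    except (KeyError, ValueError) as exc:
        raise KBParseError(f"bad premise: {exc}", path) from exc


def save_kb(kb: KnowledgeBase) -> str:
    """Serialize a knowledge base to its YAML document form."""
    doc: dict = {
        "name": kb.name,
        "version": kb.version,
        "concepts": [],
        "hierarchy": [{"child": l.child_id, "parent": l.parent_id} for l in kb.hierarchy],
        "rules": [],
    }
    for c in kb.concepts:
        obj: dict = {"id": c.id, "label": c.label, "value_kind": c.value_kind.value}
        if c.units is not None:
            obj["units"] = c.units
        if c.fhir_annotation is not None:
            obj["fhir"] = {
                "resource_type": c.fhir_annotation.resource_type,
                "code_system": c.fhir_annotation.code_system,
                "code": c.fhir_annotation.code,
            }
        if c.snomed_annotation is not None:
            obj["snomed"] = c.snomed_annotation
        if c.chronic:
            obj["chronic"] = True
        if c.section is not None:
            obj["section"] = c.section
        doc["concepts"].append(obj)
    for r in kb.rules:
        s = r.statement
        robj: dict = {
            "id": r.id,
            "kind": r.kind.value,
            "expr": _expr_to_obj(r.expr),
            "statement": {
                "text": s.text,
                "category": s.category.value,
                "evidence": {
                    k: v
                    for k, v in (
                        ("source_document", s.evidence.source_document),
                        ("section", s.evidence.section),
                        ("page", s.evidence.page),
                        ("evidence_level", s.evidence.evidence_level),
                    )
                    if v is not None
                },
            },
        }
        doc["rules"].append(robj)
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True, width=100)


def _require(obj: dict, key: str, path: str) -> object:
    if key not in obj:
        raise KBParseError(f"missing required field {key!r}", path)
    return obj[key]


def load_kb(source: Union[str, Path, io.TextIOBase]) -> KnowledgeBase:
    """Parse and validate a knowledge-base document.

    ``source`` may be a YAML string, a path to a YAML file, or an open
    text stream.  Raises :class:`KBParseError` on schema violations
    (naming the offending path) and :class:`KBValidationError` when the
    parsed KB fails :func:`validate_kb`.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml")):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = source

    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise KBParseError(f"not valid YAML: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise KBParseError("document root must be a mapping")

    concepts = []
    for i, obj in enumerate(doc.get("concepts") or []):
        path = f"$.concepts[{i}]"
        if not isinstance(obj, dict):
            raise KBParseError("concept must be a mapping", path)
        try:
            fhir = None
            if "fhir" in obj:
                fhir = FhirAnnotation(**obj["fhir"])
            concepts.append(
                ClinicalConcept(
                    id=str(_require(obj, "id", path)),
                    label=str(_require(obj, "label", path)),
                    value_kind=ValueKind(obj.get("value_kind", "boolean")),
                    units=obj.get("units"),
                    fhir_annotation=fhir,
                    snomed_annotation=(
                        str(obj["snomed"]) if obj.get("snomed") is not None else None
                    ),
                    chronic=bool(obj.get("chronic", False)),
                    section=obj.get("section"),
                )
            )
        except (TypeError, ValueError) as exc:
            raise KBParseError(f"bad concept: {exc}", path) from exc

    hierarchy = []
    for i, obj in enumerate(doc.get("hierarchy") or []):
        path = f"$.hierarchy[{i}]"
        if not isinstance(obj, dict):
            raise KBParseError("hierarchy link must be a mapping", path)
        hierarchy.append(
            HierarchyLink(
                child_id=str(_require(obj, "child", path)),
                parent_id=str(_require(obj, "parent", path)),
            )
        )

    rules = []
    for i, obj in enumerate(doc.get("rules") or []):
        path = f"$.rules[{i}]"
        if not isinstance(obj, dict):
            raise KBParseError("rule must be a mapping", path)
        sobj = _require(obj, "statement", path)
        if not isinstance(sobj, dict):
            raise KBParseError("statement must be a mapping", f"{path}.statement")
        try:
            evidence = EvidenceRef(**(sobj.get("evidence") or {}))
            statement = ClinicalStatement(
                text=str(_require(sobj, "text", f"{path}.statement")),
                category=StatementCategory(sobj.get("category", "prescribe")),
                evidence=evidence,
            )
            rules.append(
                Rule(
                    id=str(_require(obj, "id", path)),
                    kind=RuleKind(_require(obj, "kind", path)),
                    expr=_expr_from_obj(_require(obj, "expr", path), f"{path}.expr"),
                    statement=statement,
                )
            )
        except (TypeError, ValueError) as exc:
            raise KBParseError(f"bad rule: {exc}", path) from exc

    kb = KnowledgeBase(
        name=str(doc.get("name", "knowledge-base")),
        version=str(doc.get("version", "0")),
        concepts=tuple(concepts),
        hierarchy=tuple(hierarchy),
        rules=tuple(rules),
    )
    issues = validate_kb(kb)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise KBValidationError(errors)
    return kb


def kb_json_schema() -> dict:
    """JSON Schema for the in-memory KB model (generated from pydantic)."""
    return KnowledgeBase.model_json_schema()
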
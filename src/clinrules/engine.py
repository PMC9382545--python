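"""Rule evaluation under strong Kleene semantics, with counterfactuals.

Each rule's premise expression is evaluated against a patient's fact
base.  A rule whose expression is TRUE *fires*: its clinical statement
becomes a recommendation carrying the satisfied premises as the
justification the professional can inspect.  A rule whose expression is
UNKNOWN cannot be decided from the record; for those, a counterfactual
analysis enumerates both resolutions of every unknown premise and
reports which missing items are actually decision-relevant — i.e. where
completing the record could change whether the rule fires.

Recommendations never assert new facts: there is no forward chaining.
"""

from __future__ import annotations

from typing import Optional, Union

from pydantic import BaseModel, ConfigDict

from .knowledge import (
    Comparator,
    KnowledgeBase,
    Node,
    Premise,
    PremiseExpr,
    ClinicalStatement,
    Connective,
    EvidenceRef,
    Rule,
    StatementCategory,
    iter_leaves,
)
from .logic import TruthValue, kleene_and, kleene_or
from .patient import FactBase, PatientRecord, build_facts

__all__ = [
    "EvaluationTypeError",
    "TooManyUnknownsError",
    "SatisfiedPremise",
    "RuleOutcome",
    "Recommendation",
    "CounterfactualReport",
    "EvaluationResult",
    "eval_premise",
    "eval_expr",
    "evaluate_rule",
    "counterfactual_analysis",
    "evaluate_patient",
]


class EvaluationTypeError(TypeError):
    """A comparator was applied to a fact of the wrong kind."""


class TooManyUnknownsError(ValueError):
    """Counterfactual enumeration refused: too many unknown atoms."""

    def __init__(self, rule_id: str, n_unknowns: int, limit: int) -> None:
        self.rule_id = rule_id
        self.n_unknowns = n_unknowns
        self.limit = limit
        super().__init__(
            f"rule {rule_id!r} has {n_unknowns} unknown atoms; "
            f"enumeration limit is {limit}"
        )


def eval_premise(premise: Premise, facts: FactBase) -> TruthValue:
    """Apply the premise's comparator to the observed fact.

    UNKNOWN facts yield UNKNOWN for every comparator.  A comparator that
    does not fit the stored fact kind (e.g. an ordering comparator on a
    boolean fact) raises :class:`EvaluationTypeError`.
    """
    fact = facts.value(premise.concept_id)
    if fact is TruthValue.UNKNOWN:
        return TruthValue.UNKNOWN

    cmp = premise.comparator
    if cmp in (Comparator.IS_TRUE, Comparator.IS_FALSE):
        if not isinstance(fact, TruthValue):
            raise EvaluationTypeError(
                f"{cmp.value} applied to non-boolean fact {premise.concept_id!r}"
            )
        wanted = TruthValue.TRUE if cmp is Comparator.IS_TRUE else TruthValue.FALSE
        return TruthValue.from_bool(fact is wanted)

    if isinstance(fact, TruthValue):
        raise EvaluationTypeError(
            f"{cmp.value} applied to boolean fact {premise.concept_id!r}"
        )

    value = premise.value
    if cmp is Comparator.EQ:
        return TruthValue.from_bool(fact == value)
    if cmp is Comparator.NE:
        return TruthValue.from_bool(fact != value)

    if not isinstance(fact, (int, float)) or isinstance(fact, bool):
        raise EvaluationTypeError(
            f"{cmp.value} applied to non-numeric fact {premise.concept_id!r}"
        )
    if cmp is Comparator.LT:
        return TruthValue.from_bool(fact < value)
    if cmp is Comparator.LE:
        return TruthValue.from_bool(fact <= value)
    if cmp is Comparator.GT:
        return TruthValue.from_bool(fact > value)
    if cmp is Comparator.GE:
        return TruthValue.from_bool(fact >= value)
    if cmp is Comparator.BETWEEN:
        low, high = value
        return TruthValue.from_bool(low <= fact <= high)
    raise AssertionError(f"unhandled comparator {cmp!r}")


def eval_expr(
    expr: PremiseExpr,
    facts: FactBase,
    overrides: Optional[dict[tuple, TruthValue]] = None,
) -> TruthValue:
    """Evaluate an expression tree under strong Kleene semantics.

    ``overrides`` maps premise keys (see :meth:`Premise.key`) to forced
    truth values; the counterfactual analysis uses it to resolve unknown
    premises without touching the fact base.
    """
    if isinstance(expr, Premise):
        if overrides is not None:
            forced = overrides.get(expr.key())
            if forced is not None:
                return forced
        return eval_premise(expr, facts)
    values = (eval_expr(child, facts, overrides) for child in expr.children)
    if expr.op is Connective.AND:
        return kleene_and(values)
    return kleene_or(values)


class SatisfiedPremise(BaseModel):
    """One fulfilled premise, shown in the recommendation's justification."""

    model_config = ConfigDict(frozen=True)

    concept_id: str
    comparator: Comparator
    value: Union[bool, int, float, str, tuple, list, None] = None
    observed: Union[bool, int, float, str, None] = None


class RuleOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)

    rule_id: str
    truth: TruthValue
    satisfied_premises: tuple[SatisfiedPremise, ...] = ()
    unknown_premises: tuple[str, ...] = ()


class Recommendation(BaseModel):
    """A fired clinical statement with its justification and evidence."""

    model_config = ConfigDict(frozen=True)

    rule_id: str
    statement: ClinicalStatement
    justification: tuple[SatisfiedPremise, ...]

    @property
    def evidence(self) -> EvidenceRef:
        return self.statement.evidence


class CounterfactualReport(BaseModel):
    """What completing the record could do for one undecided rule.

    ``fire_possible`` — some resolution of the unknown premises makes
    the rule fire; ``fire_certain`` — every resolution does;
    ``decision_relevant_atoms`` — unknown concepts whose resolution can,
    in some context of the others, change whether the rule fires.
    """

    model_config = ConfigDict(frozen=True)

    rule_id: str
    unknown_atoms: tuple[str, ...]
    decision_relevant_atoms: tuple[str, ...]
    fire_possible: bool
    fire_certain: bool


class EvaluationResult(BaseModel):
    """Grouped outcome of evaluating every rule of a KB for one patient.

    ``prescribe_group`` holds prescribe and monitor statements (the two
    are displayed together as prescribing advice), ``deprescribe_group``
    holds deprescription statements, and ``not_evaluable`` holds the
    counterfactual reports for rules undecidable from the record.
    """

    model_config = ConfigDict(frozen=True)

    prescribe_group: tuple[Recommendation, ...]
    deprescribe_group: tuple[Recommendation, ...]
    not_evaluable: tuple[CounterfactualReport, ...]
    outcomes: tuple[RuleOutcome, ...]

    @property
    def recommendations(self) -> tuple[Recommendation, ...]:
        return self.prescribe_group + self.deprescribe_group


def _observed(facts: FactBase, concept_id: str):
    v = facts.value(concept_id)
    if isinstance(v, TruthValue):
        return {TruthValue.TRUE: True, TruthValue.FALSE: False}.get(v)
    return v


def evaluate_rule(rule: Rule, facts: FactBase) -> RuleOutcome:
    """Evaluate one rule, collecting satisfied and unknown premises."""
    truth = eval_expr(rule.expr, facts)
    satisfied: list[SatisfiedPremise] = []
    unknown: list[str] = []
    seen_sat: set[tuple] = set()
    for leaf in iter_leaves(rule.expr):
        lv = eval_premise(leaf, facts)
        if lv is TruthValue.TRUE and leaf.key() not in seen_sat:
            seen_sat.add(leaf.key())
            satisfied.append(
                SatisfiedPremise(
                    concept_id=leaf.concept_id,
                    comparator=leaf.comparator,
                    value=leaf.value,
                    observed=_observed(facts, leaf.concept_id),
                )
            )
        elif lv is TruthValue.UNKNOWN and leaf.concept_id not in unknown:
            unknown.append(leaf.concept_id)
    return RuleOutcome(
        rule_id=rule.id,
        truth=truth,
        satisfied_premises=tuple(satisfied),
        unknown_premises=tuple(unknown),
    )


def counterfactual_analysis(
    rule: Rule, facts: FactBase, max_unknowns: int = 16
) -> CounterfactualReport:
    """Missing-information what-if analysis for one rule.

    Every unknown premise of the rule is an *atom* that the record could
    resolve either way (the premise satisfied or not).  All 2^k
    resolutions are enumerated; an atom is decision-relevant iff two
    resolutions differing only in that atom differ in whether the rule
    fires.  Distinct premises over the same concept resolve
    independently.  Enumeration refuses beyond ``max_unknowns`` atoms.
    """
    atoms: list[tuple] = []
    atom_concepts: list[str] = []
    for leaf in iter_leaves(rule.expr):
        if eval_premise(leaf, facts) is TruthValue.UNKNOWN and leaf.key() not in atoms:
            atoms.append(leaf.key())
            atom_concepts.append(leaf.concept_id)
    k = len(atoms)
    if k > max_unknowns:
        raise TooManyUnknownsError(rule.id, k, max_unknowns)

    fires: list[bool] = []
    for mask in range(1 << k):
        overrides = {
            atom: (TruthValue.TRUE if mask >> i & 1 else TruthValue.FALSE)
            for i, atom in enumerate(atoms)
        }
        fires.append(eval_expr(rule.expr, facts, overrides) is TruthValue.TRUE)

    relevant: list[str] = []
    for i, concept_id in enumerate(atom_concepts):
        flips = any(fires[mask] != fires[mask ^ (1 << i)] for mask in range(1 << k))
        if flips and concept_id not in relevant:
            relevant.append(concept_id)

    unknown_concepts: list[str] = []
    for cid in atom_concepts:
        if cid not in unknown_concepts:
            unknown_concepts.append(cid)

    return CounterfactualReport(
        rule_id=rule.id,
        unknown_atoms=tuple(unknown_concepts),
        decision_relevant_atoms=tuple(relevant),
        fire_possible=any(fires),
        fire_certain=all(fires),
    )


def evaluate_patient(
    kb: KnowledgeBase,
    patient: PatientRecord,
    facts: Optional[FactBase] = None,
    max_unknowns: int = 16,
) -> EvaluationResult:
    """Run every rule of ``kb`` against ``patient``.

    Rules are processed in rule-id order so output is deterministic.
    TRUE rules become recommendations in their category group; UNKNOWN
    rules become counterfactual reports; FALSE rules appear only in the
    raw outcome list.
    """
    if facts is None:
        facts = build_facts(patient, kb)

    prescribe: list[Recommendation] = []
    deprescribe: list[Recommendation] = []
    not_evaluable: list[CounterfactualReport] = []
    outcomes: list[RuleOutcome] = []

    for rule in sorted(kb.rules, key=lambda r: r.id):
        outcome = evaluate_rule(rule, facts)
        outcomes.append(outcome)
        if outcome.truth is TruthValue.TRUE:
            rec = Recommendation(
                rule_id=rule.id,
                statement=rule.statement,
                justification=outcome.satisfied_premises,
            )
            if rule.statement.category is StatementCategory.DEPRESCRIBE:
                deprescribe.append(rec)
            else:
                prescribe.append(rec)
        elif outcome.truth is TruthValue.UNKNOWN:
            not_evaluable.append(counterfactual_analysis(rule, facts, max_unknowns))

    return EvaluationResult(
        prescribe_group=tuple(prescribe),
        deprescribe_group=tuple(deprescribe),
        not_evaluable=tuple(not_evaluable),
        outcomes=tuple(outcomes),
    )
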
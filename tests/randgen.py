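"""Seeded random generators for property tests.

Builds small valid knowledge bases, fact bases and rules directly from
a `random.Random` stream, independently of the package's own synthetic
patient generator, so engine properties are exercised on structures the
fixtures never produce.
"""

from __future__ import annotations

import random

from clinrules import (
    ClinicalConcept,
    ClinicalStatement,
    Comparator,
    Connective,
    EvidenceRef,
    FactBase,
    HierarchyLink,
    KnowledgeBase,
    Node,
    Premise,
    Rule,
    RuleKind,
    StatementCategory,
    TruthValue,
    ValueKind,
)
from clinrules.patient import Provenance


def random_concepts(rng: random.Random, n: int) -> list[ClinicalConcept]:
    concepts = []
    for i in range(n):
        roll = rng.random()
        if roll < 0.7:
            kind, units = ValueKind.BOOLEAN, None
        elif roll < 0.9:
            kind, units = ValueKind.NUMBER, rng.choice([None, "points", "years"])
        else:
            kind, units = ValueKind.CATEGORY, None
        concepts.append(
            ClinicalConcept(
                id=f"c{i:03d}",
                label=f"Concept {i}",
                value_kind=kind,
                units=units,
                snomed_annotation=str(rng.randrange(10**6, 10**9)) if rng.random() < 0.5 else None,
                chronic=kind is ValueKind.BOOLEAN and rng.random() < 0.4,
            )
        )
    return concepts


def random_premise(rng: random.Random, concepts: list[ClinicalConcept]) -> Premise:
    c = rng.choice(concepts)
    if c.value_kind is ValueKind.BOOLEAN:
        return Premise(
            concept_id=c.id,
            comparator=rng.choice([Comparator.IS_TRUE, Comparator.IS_FALSE]),
        )
    if c.value_kind is ValueKind.NUMBER:
        cmp = rng.choice(
            [Comparator.EQ, Comparator.NE, Comparator.LT, Comparator.LE,
             Comparator.GT, Comparator.GE, Comparator.BETWEEN]
        )
        if cmp is Comparator.BETWEEN:
            low = rng.randrange(0, 10)
            return Premise(concept_id=c.id, comparator=cmp, value=(low, low + rng.randrange(0, 10)))
        return Premise(concept_id=c.id, comparator=cmp, value=rng.randrange(0, 15))
    return Premise(
        concept_id=c.id,
        comparator=rng.choice([Comparator.EQ, Comparator.NE]),
        value=rng.choice(["a", "b", "c"]),
    )


def random_expr(rng: random.Random, concepts: list[ClinicalConcept], depth: int):
    if depth <= 0 or rng.random() < 0.35:
        return random_premise(rng, concepts)
    n_children = rng.choice([2, 2, 3])
    return Node(
        op=rng.choice([Connective.AND, Connective.OR]),
        children=tuple(random_expr(rng, concepts, depth - 1) for _ in range(n_children)),
    )


def random_rule(rng: random.Random, concepts: list[ClinicalConcept], rule_id: str, depth: int = 3) -> Rule:
    expr = random_expr(rng, concepts, depth)
    return Rule(
        id=rule_id,
        kind=RuleKind.MINI if isinstance(expr, Premise) else RuleKind.SUPER,
        expr=expr,
        statement=ClinicalStatement(
            text=f"Statement for {rule_id}",
            category=rng.choice(list(StatementCategory)),
            evidence=EvidenceRef(source_document=f"Source {rng.randrange(5)}"),
        ),
    )


def random_kb(rng: random.Random, n_concepts: int = 8, n_rules: int = 4) -> KnowledgeBase:
    concepts = random_concepts(rng, n_concepts)
    boolean_ids = [c.id for c in concepts if c.value_kind is ValueKind.BOOLEAN]
    hierarchy = []
    # child index < parent index keeps the is-a graph acyclic
    for i, child in enumerate(boolean_ids[:-1]):
        if rng.random() < 0.3:
            hierarchy.append(
                HierarchyLink(child_id=child, parent_id=rng.choice(boolean_ids[i + 1:]))
            )
    rules = tuple(random_rule(rng, concepts, f"r{i:03d}") for i in range(n_rules))
    return KnowledgeBase(
        name=f"random-{rng.randrange(10**6)}",
        version="1",
        concepts=tuple(concepts),
        hierarchy=tuple(hierarchy),
        rules=rules,
    )


def random_facts(rng: random.Random, kb: KnowledgeBase, unknown_prob: float = 0.3) -> FactBase:
    assignments = {}
    provenance = {}
    for c in kb.concepts:
        if rng.random() < unknown_prob:
            assignments[c.id] = TruthValue.UNKNOWN
            provenance[c.id] = Provenance.DEFAULT_POLICY
            continue
        provenance[c.id] = Provenance.ASSERTED
        if c.value_kind is ValueKind.BOOLEAN:
            assignments[c.id] = rng.choice([TruthValue.TRUE, TruthValue.FALSE])
        elif c.value_kind is ValueKind.NUMBER:
            assignments[c.id] = rng.randrange(0, 15)
        else:
            assignments[c.id] = rng.choice(["a", "b", "c"])
    return FactBase(assignments=assignments, provenance=provenance)


def resolve_unknowns(rng: random.Random, kb: KnowledgeBase, facts: FactBase) -> FactBase:
    """A copy of ``facts`` with every UNKNOWN entry resolved randomly."""
    assignments = dict(facts.assignments)
    provenance = dict(facts.provenance)
    for c in kb.concepts:
        if assignments[c.id] is TruthValue.UNKNOWN:
            provenance[c.id] = Provenance.ASSERTED
            if c.value_kind is ValueKind.BOOLEAN:
                assignments[c.id] = rng.choice([TruthValue.TRUE, TruthValue.FALSE])
            elif c.value_kind is ValueKind.NUMBER:
                assignments[c.id] = rng.randrange(0, 15)
            else:
                assignments[c.id] = rng.choice(["a", "b", "c"])
    return FactBase(assignments=assignments, provenance=provenance)
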
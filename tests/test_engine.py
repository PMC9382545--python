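"""Three-valued rule evaluation, counterfactuals, and their invariants."""

import itertools
import random

import pytest

from clinrules import (
    Comparator,
    Connective,
    FactBase,
    KnowledgeBase,
    Node,
    Premise,
    TruthValue,
    counterfactual_analysis,
    eval_expr,
    eval_premise,
    evaluate_patient,
)
from clinrules.engine import (
    EvaluationTypeError,
    TooManyUnknownsError,
    evaluate_rule,
)
from clinrules.patient import PatientRecord, Provenance, RecordPolicy

import oracles
import randgen

T, F, U = TruthValue.TRUE, TruthValue.FALSE, TruthValue.UNKNOWN

#: numeric encoding of strong Kleene: AND is min, OR is max under F < U < T
_RANK = {F: 0, U: 1, T: 2}
_BY_RANK = {v: k for k, v in _RANK.items()}


def _bool_facts(**assignments) -> FactBase:
    return FactBase(
        assignments=dict(assignments),
        provenance={k: Provenance.ASSERTED for k in assignments},
    )


def _leaf(cid: str) -> Premise:
    return Premise(concept_id=cid, comparator=Comparator.IS_TRUE)


class TestEvalPremise:
    def test_boolean_comparators(self):
        facts = _bool_facts(a=T, b=F, c=U)
        assert eval_premise(_leaf("a"), facts) is T
        assert eval_premise(_leaf("b"), facts) is F
        assert eval_premise(_leaf("c"), facts) is U
        is_false = Premise(concept_id="b", comparator=Comparator.IS_FALSE)
        assert eval_premise(is_false, facts) is T

    def test_worked_example_premises(self, kb, facts0):
        # no ticlopidine in the record; closed policy makes the premise FALSE
        ticlo = Premise(concept_id="ticlopidine", comparator=Comparator.IS_TRUE)
        assert eval_premise(ticlo, facts0) is F
        # age 70 satisfies the >= 65 inclusion threshold
        age = Premise(concept_id="age", comparator=Comparator.GE, value=65)
        assert eval_premise(age, facts0) is T
        # HAS-BLED was never recorded: threshold premise is undecidable
        bled = Premise(concept_id="has_bled", comparator=Comparator.GE, value=3)
        assert eval_premise(bled, facts0) is U

    @pytest.mark.parametrize(
        "comparator, value, observed, expected",
        [
            (Comparator.EQ, 3, 3, T),
            (Comparator.NE, 3, 3, F),
            (Comparator.LT, 5, 4, T),
            (Comparator.LE, 4, 4, T),
            (Comparator.GT, 4, 4, F),
            (Comparator.GE, 4, 5, T),
            (Comparator.BETWEEN, (2, 5), 5, T),
            (Comparator.BETWEEN, (2, 5), 6, F),
        ],
    )
    def test_numeric_comparators(self, comparator, value, observed, expected):
        facts = _bool_facts(x=observed)
        premise = Premise(concept_id="x", comparator=comparator, value=value)
        assert eval_premise(premise, facts) is expected

    def test_type_mismatch_raises(self):
        facts = _bool_facts(flag=T, score=4)
        with pytest.raises(EvaluationTypeError):
            eval_premise(Premise(concept_id="flag", comparator=Comparator.GE, value=1), facts)
        with pytest.raises(EvaluationTypeError):
            eval_premise(Premise(concept_id="score", comparator=Comparator.IS_TRUE), facts)


class TestKleeneSemantics:
    """eval_expr matches the full strong Kleene truth tables, exhaustively."""

    @pytest.mark.parametrize("op", [Connective.AND, Connective.OR])
    def test_binary_tables(self, op):
        for va, vb in itertools.product([T, F, U], repeat=2):
            facts = _bool_facts(a=va, b=vb)
            expr = Node(op=op, children=(_leaf("a"), _leaf("b")))
            agg = min if op is Connective.AND else max
            expected = _BY_RANK[agg(_RANK[va], _RANK[vb])]
            assert eval_expr(expr, facts) is expected, (op, va, vb)

    @pytest.mark.parametrize("op", [Connective.AND, Connective.OR])
    def test_ternary_tables(self, op):
        for combo in itertools.product([T, F, U], repeat=3):
            facts = _bool_facts(a=combo[0], b=combo[1], c=combo[2])
            expr = Node(op=op, children=(_leaf("a"), _leaf("b"), _leaf("c")))
            agg = min if op is Connective.AND else max
            expected = _BY_RANK[agg(_RANK[v] for v in combo)]
            assert eval_expr(expr, facts) is expected, (op, combo)

    def test_noac_rule_on_worked_example(self, kb, facts0):
        # atrial fibrillation present, but neither mitral stenosis nor a
        # mechanical valve: the NOAC contraindication rule is refuted
        rule = next(r for r in kb.rules if r.id == "r11")
        assert eval_expr(rule.expr, facts0) is F

    @pytest.mark.parametrize("seed", range(60))
    def test_depth3_expressions_match_truth_table_oracle(self, seed):
        """Random nested expressions agree with the min/max rank oracle on
        every assignment of their leaves."""
        from clinrules import ClinicalConcept

        rng = random.Random(seed)
        cids = [f"x{i}" for i in range(4)]
        bool_concepts = [ClinicalConcept(id=cid, label=cid) for cid in cids]
        expr = randgen.random_expr(rng, bool_concepts, depth=3)

        def rank_eval(e, facts):
            if isinstance(e, Premise):
                return _RANK[eval_premise(e, facts)]
            ranks = [rank_eval(c, facts) for c in e.children]
            return min(ranks) if e.op is Connective.AND else max(ranks)

        for combo in itertools.product([T, F, U], repeat=len(cids)):
            facts = _bool_facts(**dict(zip(cids, combo)))
            assert eval_expr(expr, facts) is _BY_RANK[rank_eval(expr, facts)]


class TestCounterfactual:
    def test_noac_rule_with_unknown_stenosis(self, kb):
        """Atrial fibrillation established, mitral stenosis unrecorded,
        mechanical valve refuted: completing the stenosis item decides
        the rule."""
        rule = next(r for r in kb.rules if r.id == "r11")
        facts = _bool_facts(
            atrial_fibrillation=T, mitral_stenosis=U, mechanical_heart_valve=F
        )
        report = counterfactual_analysis(rule, facts)
        assert report.fire_possible and not report.fire_certain
        assert report.unknown_atoms == ("mitral_stenosis",)
        assert report.decision_relevant_atoms == ("mitral_stenosis",)

    def test_rule_already_true(self, kb, facts0):
        rule = next(r for r in kb.rules if r.id == "r01")
        report = counterfactual_analysis(rule, facts0)
        assert report.fire_possible and report.fire_certain
        assert report.decision_relevant_atoms == ()

    def test_false_conjunct_dominates_unknowns(self, kb):
        rule = next(r for r in kb.rules if r.id == "r11")
        facts = _bool_facts(
            atrial_fibrillation=F, mitral_stenosis=U, mechanical_heart_valve=U
        )
        report = counterfactual_analysis(rule, facts)
        assert not report.fire_possible and not report.fire_certain
        assert report.decision_relevant_atoms == ()

    def test_too_many_unknowns_refused(self):
        from clinrules import ClinicalStatement, EvidenceRef, Rule, RuleKind, StatementCategory

        cids = [f"x{i}" for i in range(5)]
        facts = _bool_facts(**{c: U for c in cids})
        expr = Node(op=Connective.OR, children=tuple(_leaf(c) for c in cids))
        rule = Rule(
            id="r0",
            kind=RuleKind.SUPER,
            expr=expr,
            statement=ClinicalStatement(
                text="t",
                category=StatementCategory.MONITOR,
                evidence=EvidenceRef(source_document="s"),
            ),
        )
        with pytest.raises(TooManyUnknownsError, match="r0"):
            counterfactual_analysis(rule, facts, max_unknowns=4)

    def test_matches_brute_force_oracle_on_generated_rules(self):
        """counterfactual_analysis agrees with exhaustive enumeration for
        hundreds of generated rules with up to 8 unknown atoms."""
        rng = random.Random(20240901)
        checked = 0
        while checked < 500:
            kb = randgen.random_kb(rng, n_concepts=9, n_rules=1)
            rule = kb.rules[0]
            facts = randgen.random_facts(rng, kb, unknown_prob=rng.choice([0.2, 0.5, 0.8]))
            if oracles.count_unknown_atoms(rule, facts) > 8:
                continue
            report = counterfactual_analysis(rule, facts, max_unknowns=8)
            unknown, relevant, possible, certain = oracles.brute_force_counterfactual(rule, facts)
            assert list(report.unknown_atoms) == unknown
            assert sorted(report.decision_relevant_atoms) == relevant
            assert report.fire_possible == possible
            assert report.fire_certain == certain
            # structural invariants
            assert report.fire_possible >= report.fire_certain
            assert set(report.decision_relevant_atoms) <= set(report.unknown_atoms)
            checked += 1


class TestClassicalLimit:
    def test_three_valued_equals_two_valued_on_full_facts(self):
        """With no UNKNOWN fact, Kleene evaluation collapses to classical
        propositional evaluation (independent all/any oracle)."""
        rng = random.Random(77)
        checked = 0
        while checked < 500:
            kb = randgen.random_kb(rng, n_concepts=7, n_rules=3)
            facts = randgen.random_facts(rng, kb, unknown_prob=0.0)
            for rule in kb.rules:
                got = eval_expr(rule.expr, facts)
                expected = oracles.classical_eval(
                    rule.expr, lambda leaf: oracles.classical_leaf(leaf, facts)
                )
                assert got is (T if expected else F)
                checked += 1


class TestRefinementMonotonicity:
    def test_resolving_unknowns_never_flips_determined_rules(self):
        rng = random.Random(424242)
        checked = 0
        while checked < 500:
            kb = randgen.random_kb(rng, n_concepts=8, n_rules=3)
            facts = randgen.random_facts(rng, kb, unknown_prob=0.4)
            refined = randgen.resolve_unknowns(rng, kb, facts)
            for rule in kb.rules:
                before = eval_expr(rule.expr, facts)
                if before is U:
                    continue
                assert eval_expr(rule.expr, refined) is before
                checked += 1


class TestEvaluatePatient:
    def test_empty_kb_empty_result(self, patient0):
        result = evaluate_patient(KnowledgeBase(), patient0.model_copy(update={
            "conditions": (), "medications": (), "observations": {}}))
        assert result.recommendations == ()
        assert result.not_evaluable == ()

    def test_groups_partition_outcomes(self, kb, patient0):
        result = evaluate_patient(kb, patient0)
        rec_ids = {r.rule_id for r in result.recommendations}
        cf_ids = {c.rule_id for c in result.not_evaluable}
        false_ids = {o.rule_id for o in result.outcomes if o.truth is F}
        assert rec_ids.isdisjoint(cf_ids)
        assert rec_ids | cf_ids | false_ids == {r.id for r in kb.rules}
        assert len(rec_ids) + len(cf_ids) + len(false_ids) == len(kb.rules)

    def test_true_rules_carry_nonempty_justification(self, kb, patient0):
        result = evaluate_patient(kb, patient0)
        for rec in result.recommendations:
            assert rec.justification

    def test_output_order_is_rule_id_order(self, kb, patient0):
        result = evaluate_patient(kb, patient0)
        ids = [r.rule_id for r in result.prescribe_group]
        assert ids == sorted(ids)
        ids = [r.rule_id for r in result.deprescribe_group]
        assert ids == sorted(ids)

    @pytest.mark.parametrize("seed", range(30))
    def test_conservation_on_generated_evaluations(self, seed):
        """recommendations + counterfactual reports + FALSE rules = rules."""
        rng = random.Random(seed)
        kb = randgen.random_kb(rng, n_concepts=8, n_rules=5)
        facts = randgen.random_facts(rng, kb, unknown_prob=0.3)
        patient = PatientRecord(patient_id="p", age=70, record_policy=RecordPolicy.OPEN)
        result = evaluate_patient(kb, patient, facts=facts)
        n_false = sum(1 for o in result.outcomes if o.truth is F)
        assert len(result.recommendations) + len(result.not_evaluable) + n_false == len(kb.rules)

    def test_duplicate_statements_not_deduplicated(self, kb, patient0):
        # three distinct rules share the {AF, oral anticoagulant} premise
        # set; each carries its own statement and evidence
        result = evaluate_patient(kb, patient0)
        shared = [r for r in result.recommendations
                  if {p.concept_id for p in r.justification}
                  == {"atrial_fibrillation", "oral_anticoagulant"}]
        assert len(shared) == 3
        assert len({r.statement.text for r in shared}) == 3


class TestRuleOutcome:
    def test_satisfied_premises_report_observed_values(self, kb, facts0):
        rule = next(r for r in kb.rules if r.id == "r12")
        outcome = evaluate_rule(rule, facts0)
        assert outcome.truth is U
        sat = {p.concept_id: p for p in outcome.satisfied_premises}
        assert sat["medication_count"].observed == 14
        assert outcome.unknown_premises == ("has_bled",)
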
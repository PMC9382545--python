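"""Independent reference evaluators used as test oracles.

These deliberately avoid the engine's Kleene evaluation path: leaves
are compared with `operator` functions, connectives with `all`/`any`
over Python booleans, and counterfactuals by exhaustive enumeration
with `itertools.product`.
"""

from __future__ import annotations

import itertools
import operator

from clinrules import Comparator, Connective, Premise, TruthValue
from clinrules.knowledge import iter_leaves

_OPS = {
    Comparator.EQ: operator.eq,
    Comparator.NE: operator.ne,
    Comparator.LT: operator.lt,
    Comparator.LE: operator.le,
    Comparator.GT: operator.gt,
    Comparator.GE: operator.ge,
}


def classical_leaf(premise: Premise, facts) -> bool:
    """Two-valued premise evaluation; the fact must be determined."""
    v = facts.assignments[premise.concept_id]
    assert v is not TruthValue.UNKNOWN
    if premise.comparator is Comparator.IS_TRUE:
        return v is TruthValue.TRUE
    if premise.comparator is Comparator.IS_FALSE:
        return v is TruthValue.FALSE
    if premise.comparator is Comparator.BETWEEN:
        low, high = premise.value
        return low <= v <= high
    return _OPS[premise.comparator](v, premise.value)


def classical_eval(expr, leaf_fn) -> bool:
    """Two-valued expression evaluation via all/any."""
    if isinstance(expr, Premise):
        return leaf_fn(expr)
    results = [classical_eval(child, leaf_fn) for child in expr.children]
    return all(results) if expr.op is Connective.AND else any(results)


def count_unknown_atoms(rule, facts) -> int:
    """Distinct unknown leaf premises (the enumeration dimension)."""
    keys = set()
    for leaf in iter_leaves(rule.expr):
        if facts.assignments[leaf.concept_id] is TruthValue.UNKNOWN:
            keys.add(leaf.key())
    return len(keys)


def brute_force_counterfactual(rule, facts):
    """Exhaustive enumeration over every resolution of the unknown premises.

    Returns (unknown concept ids, decision-relevant concept ids,
    fire_possible, fire_certain); atoms are distinct unknown leaf
    premises, reported by concept id.
    """
    unknown_keys: list[tuple] = []
    for leaf in iter_leaves(rule.expr):
        if (
            facts.assignments[leaf.concept_id] is TruthValue.UNKNOWN
            and leaf.key() not in unknown_keys
        ):
            unknown_keys.append(leaf.key())

    outcomes: dict[tuple, bool] = {}
    for combo in itertools.product([False, True], repeat=len(unknown_keys)):
        mapping = dict(zip(unknown_keys, combo))

        def leaf_fn(leaf, mapping=mapping):
            if leaf.key() in mapping:
                return mapping[leaf.key()]
            return classical_leaf(leaf, facts)

        outcomes[combo] = classical_eval(rule.expr, leaf_fn)

    fires = list(outcomes.values())
    relevant: set[str] = set()
    for i, key in enumerate(unknown_keys):
        for combo, fired in outcomes.items():
            flipped = tuple(not b if j == i else b for j, b in enumerate(combo))
            if outcomes[flipped] != fired:
                relevant.add(key[0])
                break

    unknown_concepts: list[str] = []
    for key in unknown_keys:
        if key[0] not in unknown_concepts:
            unknown_concepts.append(key[0])

    return (
        unknown_concepts,
        sorted(relevant),
        any(fires),
        all(fires),
    )
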
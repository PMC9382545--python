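"""Three-valued truth values with strong Kleene (K3) connectives.

UNKNOWN propagates through a connective unless it is dominated: FALSE
dominates a conjunction, TRUE dominates a disjunction.  This is the
conservative semantics appropriate for clinical rules evaluated against
incomplete records: a rule only fires when its premises are established,
and only fails when they are refuted.
"""

from __future__ import annotations

import enum
from typing import Iterable


class TruthValue(enum.Enum):
    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    @classmethod
    def from_bool(cls, value: bool) -> "TruthValue":
        return cls.TRUE if value else cls.FALSE

    @property
    def is_determined(self) -> bool:
        return self is not TruthValue.UNKNOWN

    def __repr__(self) -> str:  # terse in test diffs
        return self.name


def kleene_and(values: Iterable[TruthValue]) -> TruthValue:
    """Strong Kleene conjunction: FALSE if any FALSE, TRUE if all TRUE."""
    result = TruthValue.TRUE
    for v in values:
        if v is TruthValue.FALSE:
            return TruthValue.FALSE
        if v is TruthValue.UNKNOWN:
            result = TruthValue.UNKNOWN
    return result


def kleene_or(values: Iterable[TruthValue]) -> TruthValue:
    """Strong Kleene disjunction: TRUE if any TRUE, FALSE if all FALSE."""
    result = TruthValue.FALSE
    for v in values:
        if v is TruthValue.TRUE:
            return TruthValue.TRUE
        if v is TruthValue.UNKNOWN:
            result = TruthValue.UNKNOWN
    return result
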
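"""Truth-table evaluation and gate classification.

A reaction system's truth table enumerates all 2^n input assignments in
canonical binary order (first-listed input is the most significant bit) and
records whether any template is active — any running template produces RCA
signal, so the Boolean output is "at least one template active".

Classification matches a table against the named catalogue after trying all
input permutations, so asymmetric gates (ANDN, ORN, YES, NOT) are reported
with the permutation that matched rather than as distinct mirror gates.
Under this symmetry the 16 two-input Boolean functions collapse onto exactly
12 names.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import permutations
from typing import Callable, Mapping, Sequence

import pandas as pd

from .core import ReactionSystem, system_activity

__all__ = [
    "TruthTable",
    "GateName",
    "GateLabel",
    "evaluate_truth_table",
    "classify_gate",
]

MAX_INPUTS = 8


@dataclass(frozen=True)
class TruthTable:
    """Ordered truth table: 2^n outputs over canonical binary row order."""

    input_names: tuple
    outputs: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_names", tuple(self.input_names))
        object.__setattr__(self, "outputs", tuple(int(b) for b in self.outputs))
        n = len(self.input_names)
        if len(set(self.input_names)) != n:
            raise ValueError("duplicate input names")
        if len(self.outputs) != 2**n:
            raise ValueError(
                f"expected {2**n} rows for {n} inputs, got {len(self.outputs)}"
            )
        if any(b not in (0, 1) for b in self.outputs):
            raise ValueError("outputs must be bits")

    @property
    def n(self) -> int:
        return len(self.input_names)

    def row_assignment(self, row: int) -> dict:
        """Input bits of row ``row``; first input is the most significant bit."""
        n = self.n
        return {
            name: (row >> (n - 1 - i)) & 1
            for i, name in enumerate(self.input_names)
        }

    @classmethod
    def from_function(
        cls, input_names: Sequence[str], fn: Callable[[Mapping[str, int]], int]
    ) -> "TruthTable":
        names = tuple(input_names)
        n = len(names)
        outputs = []
        for row in range(2**n):
            assignment = {
                name: (row >> (n - 1 - i)) & 1 for i, name in enumerate(names)
            }
            outputs.append(int(fn(assignment)))
        return cls(names, tuple(outputs))

    def permuted(self, perm: Sequence[int]) -> "TruthTable":
        """Table with inputs reordered so new input ``i`` is old input ``perm[i]``."""
        n = self.n
        if sorted(perm) != list(range(n)):
            raise ValueError(f"invalid permutation {perm!r} for {n} inputs")
        new_names = tuple(self.input_names[p] for p in perm)
        inverse = {old: new for new, old in enumerate(perm)}
        outputs = []
        for row in range(2**n):
            bits_new = [(row >> (n - 1 - i)) & 1 for i in range(n)]
            old_row = 0
            for j in range(n):
                old_row |= bits_new[inverse[j]] << (n - 1 - j)
            outputs.append(self.outputs[old_row])
        return TruthTable(new_names, tuple(outputs))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for row, out in enumerate(self.outputs):
            entry = self.row_assignment(row)
            entry["output"] = out
            rows.append(entry)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Aligned plain-text rendering."""
        frame = self.to_frame()
        return frame.to_string(index=False)


class GateName(str, Enum):
    AND = "AND"
    OR = "OR"
    NAND = "NAND"
    NOR = "NOR"
    ANDN = "ANDN"
    ORN = "ORN"
    XOR = "XOR"
    XNOR = "XNOR"
    YES = "YES"
    NOT = "NOT"
    ALL = "ALL"
    NONE = "NONE"
    THREE_INPUT_CUSTOM = "THREE_INPUT_CUSTOM"
    OTHER = "OTHER"


@dataclass(frozen=True)
class GateLabel:
    """A gate name plus the input permutation under which the table matched."""

    name: GateName
    input_permutation: tuple

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name.value} (inputs {self.input_permutation})"


# Canonical two-input output vectors, rows ordered 00, 01, 10, 11 with the
# first input as most significant bit.  Mirror orientations of the
# asymmetric gates are reached through input permutation, so together these
# twelve names cover all 16 two-input Boolean functions.
_CANONICAL_TWO_INPUT = {
    (0, 0, 0, 0): GateName.NONE,
    (0, 0, 0, 1): GateName.AND,
    (0, 0, 1, 0): GateName.ANDN,  # A AND NOT B
    (0, 0, 1, 1): GateName.YES,  # A
    (0, 1, 1, 0): GateName.XOR,
    (0, 1, 1, 1): GateName.OR,
    (1, 0, 0, 0): GateName.NOR,
    (1, 0, 0, 1): GateName.XNOR,
    (1, 0, 1, 1): GateName.ORN,  # A OR NOT B
    (1, 1, 0, 0): GateName.NOT,  # NOT A
    (1, 1, 1, 0): GateName.NAND,
    (1, 1, 1, 1): GateName.ALL,
}

# The constructed three-input gate: output 1 exactly on assignment (1, 1, 0).
_CANONICAL_THREE_INPUT = tuple(int(r == 0b110) for r in range(8))


def evaluate_truth_table(system: ReactionSystem) -> TruthTable:
    """Enumerate every input assignment; output 1 iff any template is active."""
    names = system.input_names
    n = len(names)
    if not 1 <= n <= MAX_INPUTS:
        raise ValueError(f"system has {n} inputs; supported range is 1..{MAX_INPUTS}")
    outputs = []
    for row in range(2**n):
        assignment = {
            name: (row >> (n - 1 - i)) & 1 for i, name in enumerate(names)
        }
        count, _ = system_activity(system, assignment)
        outputs.append(int(count > 0))
    return TruthTable(names, tuple(outputs))


def classify_gate(tt: TruthTable) -> GateLabel:
    """Name a two- or three-input table, canonicalizing over input order.

    Permutations are tried in lexicographic order (identity first), so the
    reported ``input_permutation`` is deterministic.  Three-input tables
    either match the constructed three-input gate (first AND second AND NOT
    third, up to permutation) or are labelled OTHER.
    """
    n = tt.n
    if n == 2:
        for perm in permutations(range(2)):
            name = _CANONICAL_TWO_INPUT.get(tt.permuted(perm).outputs)
            if name is not None:
                return GateLabel(name, tuple(perm))
        raise AssertionError("two-input catalogue is exhaustive")  # pragma: no cover
    if n == 3:
        for perm in permutations(range(3)):
            if tt.permuted(perm).outputs == _CANONICAL_THREE_INPUT:
                return GateLabel(GateName.THREE_INPUT_CUSTOM, tuple(perm))
        return GateLabel(GateName.OTHER, (0, 1, 2))
    raise ValueError(f"classification supports 2 or 3 inputs, got {n}")
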
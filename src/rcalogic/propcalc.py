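"""Propositional formulas and derivation of gates from basic modules.

The algebra mirrors the physics of the platform.  A basic module is a
two-atom formula over a metabolite atom ``m`` and a repressor atom ``r``:

* ORN module (inducer-regulated pair): ``m OR NOT r`` — RCA runs unless the
  repressor is present without its inducer;
* NAND module (anti-inducer-regulated pair): ``NOT (m AND r)`` — RCA stops
  only when repressor and anti-inducer are both present.

Gates are derived from the basic modules by three operations only:

* SUBSTITUTE — replace a module's atoms by input variables or by the
  constants TOP (species held always present) / BOT (never supplied);
* SERIES_AND — co-locate two designs' sites on one circular template
  (conjunction);
* PARALLEL_OR — put two designs on separate templates in one reaction
  (disjunction).

:func:`derive` performs a breadth-first search over this closure, returning
a shortest derivation trace whose formula is equivalent (checked
exhaustively) to the target truth table.  :func:`realize_trace` maps a trace
back onto a concrete reaction system, closing the loop between proof and
chemistry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

from .core import (
    CircularTemplate,
    OperatorSite,
    ReactionSystem,
    RegulationMode,
    SpeciesRegistry,
    SpeciesState,
)
from .defaults import DEFAULT_OPERATOR_SEQUENCES, default_registry
from .logic import TruthTable

__all__ = [
    "Formula",
    "Atom",
    "Const",
    "Not",
    "And",
    "Or",
    "TOP",
    "BOT",
    "eval_formula",
    "equivalent",
    "truth_vector",
    "ModuleKind",
    "BasicModule",
    "BASIC_MODULES",
    "TraceOp",
    "TraceStep",
    "DerivationTrace",
    "derive",
    "verify_all_thirteen",
    "realize_trace",
    "RealizationError",
]

MAX_ATOMS = 10


# ---------------------------------------------------------------------------
# Formula AST


class Formula:
    """Base class for propositional formulas over NOT, AND, OR."""

    def eval(self, assignment: Mapping[str, int]) -> int:
        raise NotImplementedError

    def atoms(self) -> frozenset:
        raise NotImplementedError


@dataclass(frozen=True)
class Atom(Formula):
    name: str

    def eval(self, assignment):
        if self.name not in assignment:
            raise KeyError(f"unbound atom {self.name!r}")
        return int(assignment[self.name])

    def atoms(self):
        return frozenset({self.name})

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class Const(Formula):
    value: bool

    def eval(self, assignment):
        return int(self.value)

    def atoms(self):
        return frozenset()

    def __str__(self):
        return "⊤" if self.value else "⊥"


@dataclass(frozen=True)
class Not(Formula):
    operand: Formula

    def eval(self, assignment):
        return 1 - self.operand.eval(assignment)

    def atoms(self):
        return self.operand.atoms()

    def __str__(self):
        return f"¬{_wrap(self.operand)}"


@dataclass(frozen=True)
class And(Formula):
    left: Formula
    right: Formula

    def eval(self, assignment):
        return self.left.eval(assignment) & self.right.eval(assignment)

    def atoms(self):
        return self.left.atoms() | self.right.atoms()

    def __str__(self):
        return f"({self.left} ∧ {self.right})"


@dataclass(frozen=True)
class Or(Formula):
    left: Formula
    right: Formula

    def eval(self, assignment):
        return self.left.eval(assignment) | self.right.eval(assignment)

    def atoms(self):
        return self.left.atoms() | self.right.atoms()

    def __str__(self):
        return f"({self.left} ∨ {self.right})"


def _wrap(f: Formula) -> str:
    return str(f) if isinstance(f, (Atom, Const, Not)) else f"({f})"


TOP = Const(True)
BOT = Const(False)


def eval_formula(f: Formula, assignment: Mapping[str, int]) -> int:
    """Standard Boolean semantics; raises ``KeyError`` on unbound atoms."""
    return f.eval(assignment)


def truth_vector(f: Formula, variables: Sequence[str]) -> tuple:
    """Outputs of ``f`` over all assignments of ``variables`` in canonical order."""
    n = len(variables)
    out = []
    for row in range(2**n):
        assignment = {
            v: (row >> (n - 1 - i)) & 1 for i, v in enumerate(variables)
        }
        out.append(f.eval(assignment))
    return tuple(out)


def equivalent(
    f: Formula, g: Formula, variables: Optional[Iterable[str]] = None
) -> bool:
    """Exhaustive equivalence over the union of both formulas' atoms."""
    names = sorted(f.atoms() | g.atoms() | set(variables or ()))
    if len(names) > MAX_ATOMS:
        raise ValueError(
            f"equivalence check limited to {MAX_ATOMS} atoms, got {len(names)}"
        )
    return truth_vector(f, names) == truth_vector(g, names)


# ---------------------------------------------------------------------------
# Basic modules


class ModuleKind(str, Enum):
    ORN = "ORN"  # inducer-regulated pair: m OR NOT r
    NAND = "NAND"  # anti-inducer-regulated pair: NOT (m AND r)


@dataclass(frozen=True)
class BasicModule:
    """One repressor-metabolite pair viewed as a two-atom formula."""

    name: str
    kind: ModuleKind

    def formula(self, m: Formula, r: Formula) -> Formula:
        if self.kind is ModuleKind.ORN:
            return Or(m, Not(r))
        return Not(And(m, r))


BASIC_MODULES = (
    BasicModule("ORN1", ModuleKind.ORN),
    BasicModule("ORN2", ModuleKind.ORN),
    BasicModule("NAND1", ModuleKind.NAND),
    BasicModule("NAND2", ModuleKind.NAND),
)


# ---------------------------------------------------------------------------
# Derivation structures

SubstValue = Union[str, Const]  # an input-variable name, TOP or BOT


def _subst_formula(value: SubstValue) -> Formula:
    return Atom(value) if isinstance(value, str) else value


def _subst_label(value: SubstValue) -> str:
    return value if isinstance(value, str) else str(value)


@dataclass(frozen=True)
class ModuleInstance:
    """A basic module with both atoms substituted."""

    module: BasicModule
    m_sub: SubstValue
    r_sub: SubstValue

    @property
    def formula(self) -> Formula:
        return self.module.formula(
            _subst_formula(self.m_sub), _subst_formula(self.r_sub)
        )

    @property
    def n_templates(self) -> int:
        return 1

    def describe(self) -> str:
        return (
            f"{self.module.name}({_subst_label(self.m_sub)}, "
            f"{_subst_label(self.r_sub)})"
        )


@dataclass(frozen=True)
class SeriesNode:
    left: "Node"
    right: "Node"

    @property
    def formula(self) -> Formula:
        return And(self.left.formula, self.right.formula)

    @property
    def n_templates(self) -> int:
        # Sites of both operands merge onto shared templates.
        return self.left.n_templates + self.right.n_templates - 1


@dataclass(frozen=True)
class ParallelNode:
    left: "Node"
    right: "Node"

    @property
    def formula(self) -> Formula:
        return Or(self.left.formula, self.right.formula)

    @property
    def n_templates(self) -> int:
        return self.left.n_templates + self.right.n_templates


Node = Union[ModuleInstance, SeriesNode, ParallelNode]


class TraceOp(str, Enum):
    SUBSTITUTE = "SUBSTITUTE"
    SERIES_AND = "SERIES_AND"
    PARALLEL_OR = "PARALLEL_OR"


@dataclass(frozen=True)
class TraceStep:
    index: int
    op: TraceOp
    operands: tuple  # module description, or indices of prior steps
    formula: Formula

    def render(self) -> str:
        if self.op is TraceOp.SUBSTITUTE:
            src = self.operands[0]
        else:
            src = f"[{self.operands[0]}] , [{self.operands[1]}]"
        return f"[{self.index}] {self.op.value:<11} {src:<28} => {self.formula}"


@dataclass(frozen=True)
class DerivationTrace:
    """How a gate is assembled from basic modules.

    ``steps`` lists substitutions and compositions in postorder; ``final``
    is the last step's formula; ``depth`` counts composition operations.
    """

    target: str
    steps: tuple
    final: Formula
    structure: Node = field(repr=False, default=None)
    depth: int = 0

    def render(self) -> str:
        lines = [f"derivation of {self.target} (depth {self.depth}):"]
        lines += [step.render() for step in self.steps]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "depth": self.depth,
            "final": str(self.final),
            "steps": [
                {
                    "index": s.index,
                    "op": s.op.value,
                    "operands": list(s.operands),
                    "formula": str(s.formula),
                }
                for s in self.steps
            ],
        }


def _steps_from_structure(node: Node) -> list:
    steps: list = []

    def walk(n: Node) -> int:
        if isinstance(n, ModuleInstance):
            idx = len(steps)
            steps.append(
                TraceStep(idx, TraceOp.SUBSTITUTE, (n.describe(),), n.formula)
            )
            return idx
        li = walk(n.left)
        ri = walk(n.right)
        op = TraceOp.SERIES_AND if isinstance(n, SeriesNode) else TraceOp.PARALLEL_OR
        idx = len(steps)
        steps.append(TraceStep(idx, op, (li, ri), n.formula))
        return idx

    walk(node)
    return steps


def _node_depth(node: Node) -> int:
    if isinstance(node, ModuleInstance):
        return 0
    return _node_depth(node.left) + _node_depth(node.right) + 1


# ---------------------------------------------------------------------------
# Bounded derivation search


def derive(
    target_tt: TruthTable,
    basis: Sequence[BasicModule] = BASIC_MODULES,
    max_depth: int = 4,
) -> Optional[DerivationTrace]:
    """Shortest derivation of a truth table from a module basis, or None.

    Search space: every basis module with its two atoms substituted by input
    variables or TOP/BOT, closed under SERIES_AND and PARALLEL_OR up to
    ``max_depth`` composition operations.  Among equally deep derivations
    ties break on (implied template count, enumeration order), making traces
    reproducible.  Not finding a derivation within the bound is a value
    (``None``), not an error.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    variables = list(target_tt.input_names)
    target_vec = tuple(target_tt.outputs)
    domain: list = list(variables) + [TOP, BOT]

    # seen: truth vector -> node (first registration wins within a cost level)
    seen: dict = {}
    by_cost: dict = {0: []}

    def register(vec: tuple, node: Node, pool: list) -> None:
        if vec not in seen:
            seen[vec] = node
            pool.append((vec, node))

    level0: list = []
    for module in basis:
        for m_sub in domain:
            for r_sub in domain:
                inst = ModuleInstance(module, m_sub, r_sub)
                register(truth_vector(inst.formula, variables), inst, level0)
    by_cost[0] = level0

    def finish(node: Node) -> DerivationTrace:
        steps = _steps_from_structure(node)
        return DerivationTrace(
            target="table",
            steps=tuple(steps),
            final=steps[-1].formula,
            structure=node,
            depth=_node_depth(node),
        )

    if target_vec in seen:
        return finish(seen[target_vec])

    for cost in range(1, max_depth + 1):
        candidates: list = []
        seq = 0
        for ca in range((cost - 1) // 2 + 1):
            cb = cost - 1 - ca
            pool_a = by_cost.get(ca, [])
            pool_b = by_cost.get(cb, [])
            for ia, (vec_a, node_a) in enumerate(pool_a):
                start = ia if ca == cb else 0
                for vec_b, node_b in pool_b[start:]:
                    and_vec = tuple(a & b for a, b in zip(vec_a, vec_b))
                    or_vec = tuple(a | b for a, b in zip(vec_a, vec_b))
                    for vec, node_cls in (
                        (and_vec, SeriesNode),
                        (or_vec, ParallelNode),
                    ):
                        if vec in seen:
                            continue
                        node = node_cls(node_a, node_b)
                        candidates.append((node.n_templates, seq, vec, node))
                        seq += 1
        pool: list = []
        for _, _, vec, node in sorted(candidates, key=lambda c: (c[0], c[1])):
            register(vec, node, pool)
        by_cost[cost] = pool
        if target_vec in seen:
            return finish(seen[target_vec])
    return None


def verify_all_thirteen(
    basis: Sequence[BasicModule] = BASIC_MODULES,
    max_depth: int = 4,
    registry: Optional[SpeciesRegistry] = None,
) -> tuple:
    """Derive every constructed gate (12 two-input + the three-input gate).

    Returns ``(count, traces)`` where ``traces`` maps gate name to its
    :class:`DerivationTrace` (or None if not found within the depth bound).
    Every returned trace is re-checked for equivalence against its target.
    """
    from .catalogue import GATE_NAMES_13, catalogue_design
    from .logic import evaluate_truth_table

    registry = registry or default_registry()
    traces = {}
    count = 0
    for gate in GATE_NAMES_13:
        target = evaluate_truth_table(catalogue_design(gate, registry))
        trace = derive(target, basis=basis, max_depth=max_depth)
        if trace is not None:
            vec = truth_vector(trace.final, list(target.input_names))
            if vec != tuple(target.outputs):  # pragma: no cover - soundness guard
                raise AssertionError(f"unsound trace for {gate}")
            trace = DerivationTrace(
                target=gate,
                steps=trace.steps,
                final=trace.final,
                structure=trace.structure,
                depth=trace.depth,
            )
            count += 1
        traces[gate] = trace
    return count, traces


# ---------------------------------------------------------------------------
# Duality: trace -> reaction system


class RealizationError(RuntimeError):
    """Raised when a trace needs more repressors of one mode than available."""


def _flatten(node: Node) -> list:
    """Distribute series over parallel: a list of site groups (templates)."""
    if isinstance(node, ModuleInstance):
        return [[node]]
    left = _flatten(node.left)
    right = _flatten(node.right)
    if isinstance(node, ParallelNode):
        return left + right
    # Series: (A1 | A2) & B  ->  A1&B | A2&B — cross product of groups.
    return [ga + gb for ga in left for gb in right]


def _normalize_leaf(leaf: ModuleInstance) -> Optional[ModuleInstance]:
    """Physically canonical form of a substituted module.

    Tautological leaves (e.g. ORN with its metabolite held present) gate
    nothing and are dropped.  A pure negation written through an ORN module,
    ``ORN(BOT, X) = NOT X``, is realized through the anti-inducer channel
    ``NAND(X, TOP)`` instead — an operator site that binds exactly when X is
    supplied — which is the natural chemistry for a negative literal and
    keeps the scarce inducer-regulated pool for positive literals.
    ``NAND`` is symmetric in its atoms, so its constant is normalized into
    the repressor slot.
    """
    f = leaf.formula
    names = sorted(f.atoms())
    if all(truth_vector(f, names)):
        return None
    if (
        leaf.module.kind is ModuleKind.ORN
        and leaf.m_sub == BOT
        and isinstance(leaf.r_sub, str)
    ):
        return ModuleInstance(
            BasicModule("NAND*", ModuleKind.NAND), leaf.r_sub, TOP
        )
    if leaf.module.kind is ModuleKind.NAND and leaf.m_sub == TOP:
        return ModuleInstance(leaf.module, leaf.r_sub, TOP)
    return leaf


def realize_trace(
    trace: DerivationTrace,
    registry: Optional[SpeciesRegistry] = None,
    input_names: Optional[Sequence[str]] = None,
) -> ReactionSystem:
    """Compile a derivation trace into a concrete reaction system.

    Each distinct substituted module is assigned one repressor of its kind
    (ORN modules draw from the inducer-regulated pool, NAND modules from the
    anti-inducer-regulated pool); the assignment is shared across templates,
    so repressor reuse across parallel branches is free while each template
    carries at most one site per repressor.  TOP-substituted atoms become
    constant species, variable atoms become input-controlled species, and
    BOT-substituted atoms are simply never supplied.
    """
    registry = registry or default_registry()
    if trace.structure is None:
        raise ValueError("trace carries no structure to realize")
    groups = [
        [leaf for leaf in map(_normalize_leaf, group) if leaf is not None]
        for group in _flatten(trace.structure)
    ]

    pools = {
        ModuleKind.ORN: [
            r.name
            for r in registry.repressors.values()
            if r.mode is RegulationMode.INDUCER_REGULATED
        ],
        ModuleKind.NAND: [
            r.name
            for r in registry.repressors.values()
            if r.mode is RegulationMode.ANTI_INDUCER_REGULATED
        ],
    }
    assignment: dict = {}  # signature -> repressor name

    def repressor_for(leaf: ModuleInstance) -> str:
        sig = (leaf.module.kind, leaf.m_sub, leaf.r_sub)
        if sig not in assignment:
            pool = pools[leaf.module.kind]
            used = {
                rep
                for (kind, _, _), rep in assignment.items()
                if kind is leaf.module.kind
            }
            free = [r for r in pool if r not in used]
            if not free:
                raise RealizationError(
                    f"no {leaf.module.kind.value}-mode repressor left for "
                    f"{leaf.describe()}"
                )
            assignment[sig] = free[0]
        return assignment[sig]

    variables = list(input_names or [])
    constant_reps: set = set()
    constant_ligs: dict = {}
    input_species: dict = {}

    def note_variable(v: str) -> None:
        if v not in variables:
            variables.append(v)
        input_species.setdefault(v, set())

    templates = []
    for gi, group in enumerate(groups):
        # Dedupe module instances that share a signature within one template
        # (A AND A = A); they would map to the same repressor and a template
        # carries at most one site per repressor.
        unique = list(
            {
                (leaf.module.kind, leaf.m_sub, leaf.r_sub): leaf
                for leaf in group
            }.values()
        )
        sites = []
        for leaf in unique:
            rep_name = repressor_for(leaf)
            rep = registry.repressor(rep_name)
            lig = rep.cognate_ligand
            seq = DEFAULT_OPERATOR_SEQUENCES.get(rep.operator_id, (None,))[0]
            sites.append(
                OperatorSite(
                    operator_id=rep.operator_id,
                    cognate_repressor=rep_name,
                    sequence=seq,
                )
            )
            if leaf.r_sub == TOP:
                constant_reps.add(rep_name)
            elif isinstance(leaf.r_sub, str):
                note_variable(leaf.r_sub)
                input_species[leaf.r_sub].add(rep_name)
            if leaf.m_sub == TOP:
                constant_ligs[lig] = registry.ligand(lig).working_concentration_mM
            elif isinstance(leaf.m_sub, str):
                note_variable(leaf.m_sub)
                input_species[leaf.m_sub].add(lig)
        templates.append(
            CircularTemplate(name=f"{trace.target}-T{gi + 1}", sites=sites)
        )

    for v in variables:
        input_species.setdefault(v, set())
    return ReactionSystem(
        name=f"derived-{trace.target}",
        templates=templates,
        constants=SpeciesState(frozenset(constant_reps), constant_ligs),
        input_map={v: frozenset(input_species[v]) for v in variables},
        registry=registry,
    )
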
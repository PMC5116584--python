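"""Compile a target truth table into a reaction-system design.

The compiler computes an exact minimal two-level cover of the target
(Quine–McCluskey prime implicants followed by an exact set cover, trivial at
the supported scale of n <= 4 inputs) and realizes it physically:

* each implicant (product term) becomes one circular template;
* a positive literal on input A becomes the operator site of an
  inducer-regulated repressor held constant, with A supplying the inducer
  (site free iff A = 1);
* a negative literal becomes the site of an anti-inducer-regulated
  repressor held constant, with A supplying the anti-inducer (site free iff
  A = 0);
* the OR over templates comes for free from template independence.

Channel assignment is the orthogonality bottleneck: each input needs its
own repressor per polarity, so a library with two repressors of each mode
supports any two-input function but cannot give three inputs a negative
literal each.  Infeasibility is reported, never silently patched.

Every feasible design is verified against its target by exhaustive
truth-table evaluation before it is returned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .core import (
    CircularTemplate,
    OperatorSite,
    ReactionSystem,
    RegulationMode,
    SpeciesRegistry,
    SpeciesState,
)
from .defaults import DEFAULT_OPERATOR_SEQUENCES, default_registry
from .logic import TruthTable, evaluate_truth_table

__all__ = [
    "Polarity",
    "LiteralChannel",
    "ChannelInfeasible",
    "Implicant",
    "SynthesisResult",
    "assign_channels",
    "synthesize",
    "verify_design",
    "minimal_cover",
    "prime_implicants",
]

MAX_SYNTH_INPUTS = 4


class Polarity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


@dataclass(frozen=True)
class LiteralChannel:
    """How one polarity of one input signal is realized chemically."""

    input_name: str
    polarity: Polarity
    repressor: str
    metabolite: str


class ChannelInfeasible(RuntimeError):
    """Raised when the library lacks repressors for a required polarity."""

    def __init__(self, polarity: Polarity, missing_inputs: Sequence[str]):
        self.polarity = polarity
        self.missing_inputs = tuple(missing_inputs)
        mode = (
            "inducer-regulated"
            if polarity is Polarity.POSITIVE
            else "anti-inducer-regulated"
        )
        super().__init__(
            f"not enough {mode} repressors: no {polarity.value} channel for "
            f"inputs {list(missing_inputs)}"
        )


@dataclass(frozen=True)
class Implicant:
    """A product term: ``literals`` maps input index -> required bit."""

    literals: Mapping[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "literals", dict(self.literals))

    def covers(self, minterm: int, n: int) -> bool:
        return all(
            ((minterm >> (n - 1 - i)) & 1) == bit
            for i, bit in self.literals.items()
        )

    def covered_minterms(self, n: int) -> frozenset:
        return frozenset(m for m in range(2**n) if self.covers(m, n))

    def sort_key(self, n: int) -> tuple:
        """Deterministic lexicographic key on the (value, mask) bit pattern."""
        mask = sum(1 << (n - 1 - i) for i in self.literals)
        value = sum(bit << (n - 1 - i) for i, bit in self.literals.items())
        return (len(self.literals), mask, value)

    def describe(self, names: Sequence[str]) -> str:
        if not self.literals:
            return "1"
        parts = [
            (names[i] if bit else f"NOT {names[i]}")
            for i, bit in sorted(self.literals.items())
        ]
        return " AND ".join(parts)


@dataclass(frozen=True)
class SynthesisResult:
    """Outcome of a synthesis run: a verified system or an infeasibility report."""

    target: TruthTable
    system: Optional[ReactionSystem] = None
    cover: tuple = ()
    channels: tuple = ()
    infeasibility: Optional[str] = None

    @property
    def feasible(self) -> bool:
        return self.system is not None


# ---------------------------------------------------------------------------
# Exact two-level minimization


def prime_implicants(minterms: Sequence[int], n: int) -> list:
    """All prime implicants of the on-set, by iterated pairwise merging."""
    if not minterms:
        return []
    # A cube is (value, mask) with mask marking don't-care positions.
    cubes = {(m, 0) for m in minterms}
    primes = set()
    while cubes:
        merged = set()
        next_cubes = set()
        cube_list = sorted(cubes)
        for i, (v1, m1) in enumerate(cube_list):
            for v2, m2 in cube_list[i + 1 :]:
                if m1 != m2:
                    continue
                diff = v1 ^ v2
                if diff and not (diff & (diff - 1)):  # single differing bit
                    next_cubes.add((v1 & ~diff, m1 | diff))
                    merged.add((v1, m1))
                    merged.add((v2, m2))
        primes |= cubes - merged
        cubes = next_cubes
    result = []
    for value, mask in sorted(primes):
        literals = {
            i: (value >> (n - 1 - i)) & 1
            for i in range(n)
            if not (mask >> (n - 1 - i)) & 1
        }
        result.append(Implicant(literals))
    return result


def minimal_cover(minterms: Sequence[int], n: int) -> list:
    """Exact minimum prime-implicant cover of the on-set.

    Brute-force over subsets in increasing size (fine at n <= 4); among
    equal-size covers the lexicographically smallest implicant key tuple
    wins, so designs are reproducible.
    """
    on_set = frozenset(minterms)
    if not on_set:
        return []
    primes = prime_implicants(sorted(on_set), n)
    coverage = [p.covered_minterms(n) & on_set for p in primes]
    order = sorted(range(len(primes)), key=lambda i: primes[i].sort_key(n))
    best: Optional[tuple] = None
    for size in range(1, len(primes) + 1):
        candidates = []
        for combo in itertools.combinations(order, size):
            covered = frozenset().union(*(coverage[i] for i in combo))
            if covered >= on_set:
                key = tuple(primes[i].sort_key(n) for i in combo)
                candidates.append((key, combo))
        if candidates:
            best = min(candidates)[1]
            break
    assert best is not None  # primes always cover the on-set
    return [primes[i] for i in best]


# ---------------------------------------------------------------------------
# Channel assignment


def assign_channels(
    input_names: Sequence[str],
    library: Optional[SpeciesRegistry] = None,
    required: Optional[Mapping[str, frozenset]] = None,
) -> dict:
    """Give each input at most one channel per polarity from the library.

    ``required`` maps input name -> set of polarities that must be realized
    (default: both for every input).  Channels consume distinct repressors;
    running out of a mode raises :class:`ChannelInfeasible` naming the
    polarity and the inputs left without it.
    """
    library = library or default_registry()
    if required is None:
        required = {
            name: frozenset({Polarity.POSITIVE, Polarity.NEGATIVE})
            for name in input_names
        }
    pools = {
        Polarity.POSITIVE: [
            r
            for r in library.repressors.values()
            if r.mode is RegulationMode.INDUCER_REGULATED
        ],
        Polarity.NEGATIVE: [
            r
            for r in library.repressors.values()
            if r.mode is RegulationMode.ANTI_INDUCER_REGULATED
        ],
    }
    plan: dict = {name: {} for name in input_names}
    for polarity in (Polarity.POSITIVE, Polarity.NEGATIVE):
        pool = list(pools[polarity])
        needing = [
            name
            for name in input_names
            if polarity in required.get(name, frozenset())
        ]
        if len(needing) > len(pool):
            raise ChannelInfeasible(polarity, needing[len(pool) :])
        for name, rep in zip(needing, pool):
            plan[name][polarity] = LiteralChannel(
                input_name=name,
                polarity=polarity,
                repressor=rep.name,
                metabolite=rep.cognate_ligand,
            )
    return plan


# ---------------------------------------------------------------------------
# Synthesis


def synthesize(
    target_tt: TruthTable,
    library: Optional[SpeciesRegistry] = None,
    false_style: str = "inducer_withheld",
) -> SynthesisResult:
    """Design a reaction system whose truth table equals ``target_tt``.

    ``false_style`` selects how the constant-false target is encoded:
    ``"inducer_withheld"`` (an inducer-regulated repressor held constant
    with its inducer never supplied) or ``"anti_inducer_constant"`` (an
    anti-inducer-regulated repressor and its anti-inducer both held
    constant).  Feasible results are always verified before return.
    """
    library = library or default_registry()
    n = target_tt.n
    if n > MAX_SYNTH_INPUTS:
        raise ValueError(f"synthesis supports up to {MAX_SYNTH_INPUTS} inputs")
    names = list(target_tt.input_names)
    minterms = [r for r, out in enumerate(target_tt.outputs) if out]

    if not minterms:
        system = _constant_false_system(target_tt, library, false_style)
        result = SynthesisResult(target_tt, system=system, cover=())
        assert verify_design(system, target_tt)
        return result

    cover = minimal_cover(minterms, n)
    cover = sorted(cover, key=lambda imp: imp.sort_key(n))

    required: dict = {name: set() for name in names}
    for imp in cover:
        for idx, bit in imp.literals.items():
            required[names[idx]].add(
                Polarity.POSITIVE if bit else Polarity.NEGATIVE
            )
    try:
        plan = assign_channels(
            names,
            library,
            required={k: frozenset(v) for k, v in required.items()},
        )
    except ChannelInfeasible as exc:
        return SynthesisResult(
            target_tt, cover=tuple(cover), infeasibility=str(exc)
        )

    used_channels: list = []
    constant_reps: set = set()
    input_species: dict = {name: set() for name in names}
    templates = []
    for ti, imp in enumerate(cover):
        sites = []
        for idx, bit in sorted(imp.literals.items()):
            polarity = Polarity.POSITIVE if bit else Polarity.NEGATIVE
            channel = plan[names[idx]][polarity]
            rep = library.repressor(channel.repressor)
            seq = DEFAULT_OPERATOR_SEQUENCES.get(rep.operator_id, (None,))[0]
            sites.append(
                OperatorSite(
                    operator_id=rep.operator_id,
                    cognate_repressor=rep.name,
                    sequence=seq,
                )
            )
            constant_reps.add(rep.name)
            input_species[channel.input_name].add(channel.metabolite)
            if channel not in used_channels:
                used_channels.append(channel)
        templates.append(
            CircularTemplate(name=f"{target_tt.input_names}-T{ti + 1}", sites=sites)
        )

    system = ReactionSystem(
        name="synthesized",
        templates=[
            CircularTemplate(name=f"T{ti + 1}", sites=t.sites)
            for ti, t in enumerate(templates)
        ],
        constants=SpeciesState(frozenset(constant_reps), {}),
        input_map={name: frozenset(input_species[name]) for name in names},
        registry=library,
    )
    if not verify_design(system, target_tt):  # pragma: no cover - soundness guard
        raise AssertionError("synthesized system failed verification")
    return SynthesisResult(
        target_tt,
        system=system,
        cover=tuple(cover),
        channels=tuple(used_channels),
    )


def _constant_false_system(
    target_tt: TruthTable, library: SpeciesRegistry, false_style: str
) -> ReactionSystem:
    if false_style == "inducer_withheld":
        mode = RegulationMode.INDUCER_REGULATED
    elif false_style == "anti_inducer_constant":
        mode = RegulationMode.ANTI_INDUCER_REGULATED
    else:
        raise ValueError(f"unknown false_style {false_style!r}")
    candidates = [r for r in library.repressors.values() if r.mode is mode]
    if not candidates:
        raise ChannelInfeasible(
            Polarity.POSITIVE
            if mode is RegulationMode.INDUCER_REGULATED
            else Polarity.NEGATIVE,
            list(target_tt.input_names),
        )
    rep = candidates[0]
    seq = DEFAULT_OPERATOR_SEQUENCES.get(rep.operator_id, (None,))[0]
    site = OperatorSite(
        operator_id=rep.operator_id, cognate_repressor=rep.name, sequence=seq
    )
    constant_ligs = {}
    if mode is RegulationMode.ANTI_INDUCER_REGULATED:
        lig = rep.cognate_ligand
        constant_ligs[lig] = library.ligand(lig).working_concentration_mM
    # Inputs exist but supply nothing; the blocking repressor never releases.
    return ReactionSystem(
        name="synthesized",
        templates=[CircularTemplate(name="T1", sites=[site])],
        constants=SpeciesState(frozenset({rep.name}), constant_ligs),
        input_map={name: frozenset() for name in target_tt.input_names},
        registry=library,
    )


def verify_design(system: ReactionSystem, target_tt: TruthTable) -> bool:
    """Exhaustive truth-table comparison of a design against its target."""
    if len(system.input_names) != target_tt.n:
        raise ValueError(
            f"design has {len(system.input_names)} inputs, target has {target_tt.n}"
        )
    return evaluate_truth_table(system).outputs == target_tt.outputs
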
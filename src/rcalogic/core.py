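"""Species, binding rules and circular-template activity.

This module is the molecular ground truth the rest of the package consumes.
Allosterically regulated repressors bind operator sites embedded in circular
single-stranded DNA templates.  A bound site stalls the strand-displacing
polymerase, so a template supports rolling circle amplification (RCA) only
when every one of its operator sites is free.

Two regulation modes exist:

* ``INDUCER_REGULATED`` (e.g. LacI, GalR): the repressor binds its operator
  by default; its inducer (IPTG, D-galactose) releases it.
* ``ANTI_INDUCER_REGULATED`` (e.g. TrpR, MetJ): the repressor binds only in
  the presence of its anti-inducer / co-repressor (L-tryptophan, SAM).

Binding is modelled as threshold-Boolean: a ligand at or above its affinity
threshold for a repressor flips that repressor's DNA-binding state.  This
keeps the logic layer exact; graded (Hill-type) occupancy is deliberately
out of scope here and partial repression enters only through the ``leak``
parameter consumed by :mod:`rcalogic.kinetics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "RegulationMode",
    "Ligand",
    "RepressorSpec",
    "SpeciesState",
    "OperatorSite",
    "CircularTemplate",
    "SpeciesRegistry",
    "ReactionSystem",
    "resolve_state",
    "site_occupied",
    "template_active",
    "occupied_sites",
    "system_activity",
    "switch_matrix",
]

_DNA_ALPHABET = set("ACGTN")


class RegulationMode(str, Enum):
    """How a metabolite switches its repressor's DNA-binding state."""

    INDUCER_REGULATED = "inducer_regulated"
    ANTI_INDUCER_REGULATED = "anti_inducer_regulated"


@dataclass(frozen=True)
class Ligand:
    """A small-molecule effector with its default working concentration (mM)."""

    name: str
    working_concentration_mM: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("ligand name must be non-empty")
        if self.working_concentration_mM < 0:
            raise ValueError(
                f"working concentration of {self.name!r} must be >= 0"
            )


@dataclass(frozen=True, eq=True)
class RepressorSpec:
    """An allosterically regulated DNA-binding repressor.

    Parameters
    ----------
    name
        Protein name (unique within a registry).
    mode
        Inducer- or anti-inducer-regulated.
    cognate_ligand
        The metabolite that regulates this repressor.
    operator_id
        Identifier of the recognition sequence this repressor binds.
    affinity_thresholds
        Minimal concentration (mM) at which each listed ligand allosterically
        switches this repressor.  The cognate ligand must be listed;
        non-cognate entries encode cross-reactivity (e.g. high D-galactose
        acting on LacI).  Unlisted ligands never switch the repressor.
    leak
        Fraction in [0, 1] of the full polymerase rate that escapes a bound
        site.  Affects only the kinetics layer, never the Boolean layer.
    """

    name: str
    mode: RegulationMode
    cognate_ligand: str
    operator_id: str
    affinity_thresholds: Mapping[str, float]
    leak: float = 0.0

    def __post_init__(self) -> None:
        if self.cognate_ligand not in self.affinity_thresholds:
            raise ValueError(
                f"repressor {self.name!r}: cognate ligand "
                f"{self.cognate_ligand!r} missing from affinity_thresholds"
            )
        if not 0.0 <= self.leak <= 1.0:
            raise ValueError(f"repressor {self.name!r}: leak must be in [0, 1]")
        for lig, thr in self.affinity_thresholds.items():
            if thr < 0:
                raise ValueError(
                    f"repressor {self.name!r}: threshold for {lig!r} must be >= 0"
                )
        object.__setattr__(self, "affinity_thresholds", dict(self.affinity_thresholds))

    def is_switched_by(self, ligand: str, concentration_mM: float) -> bool:
        """Whether ``ligand`` at the given concentration flips this repressor."""
        thr = self.affinity_thresholds.get(ligand, math.inf)
        return concentration_mM >= thr


@dataclass(frozen=True)
class SpeciesState:
    """Which repressors are present and each ligand's concentration (mM).

    Absent ligands are concentration 0; zero entries are dropped so states
    compare canonically.
    """

    repressors_present: frozenset = frozenset()
    ligand_concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for name, conc in self.ligand_concentrations.items():
            if conc < 0:
                raise ValueError(f"ligand {name!r}: concentration must be >= 0")
            if conc > 0:
                cleaned[name] = float(conc)
        object.__setattr__(self, "ligand_concentrations", cleaned)
        object.__setattr__(
            self, "repressors_present", frozenset(self.repressors_present)
        )

    def concentration(self, ligand: str) -> float:
        return self.ligand_concentrations.get(ligand, 0.0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpeciesState):
            return NotImplemented
        return (
            self.repressors_present == other.repressors_present
            and self.ligand_concentrations == other.ligand_concentrations
        )


@dataclass(frozen=True)
class OperatorSite:
    """One repressor recognition sequence placed on a template.

    ``sequence`` may be omitted in the logic layer and resolved later from an
    operator database when sequences are actually needed.
    """

    operator_id: str
    cognate_repressor: str
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if not self.sequence:
                raise ValueError("operator sequence must be non-empty when given")
            bad = set(self.sequence) - _DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"operator {self.operator_id!r}: non-IUPAC characters {sorted(bad)}"
                )


@dataclass(frozen=True)
class CircularTemplate:
    """An ordered set of operator sites on a circular single strand.

    Site order is circular: rotating the order yields the same physical
    molecule (see :meth:`rotated`), and the Boolean layer never depends on
    order at all.  At most one site per repressor is allowed on a template.
    """

    name: str
    sites: Sequence[OperatorSite] = ()
    spacers: Sequence[int] = ()
    primer_region: str = ""
    total_length: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))
        spacers = tuple(self.spacers) if self.spacers else (6,) * len(self.sites)
        if len(spacers) != len(self.sites):
            raise ValueError(
                f"template {self.name!r}: need one spacer length per site"
            )
        object.__setattr__(self, "spacers", spacers)
        reps = [s.cognate_repressor for s in self.sites]
        if len(reps) != len(set(reps)):
            raise ValueError(
                f"template {self.name!r}: one site per repressor per template"
            )

    def rotated(self, k: int) -> "CircularTemplate":
        """The same circular molecule with the site list rotated by ``k``."""
        n = len(self.sites)
        if n == 0:
            return self
        k %= n
        return CircularTemplate(
            name=self.name,
            sites=self.sites[k:] + self.sites[:k],
            spacers=tuple(self.spacers[k:] + self.spacers[:k]),
            primer_region=self.primer_region,
            total_length=self.total_length,
        )


@dataclass(frozen=True)
class SpeciesRegistry:
    """Name-unique lookup of ligands and repressors."""

    ligands: Mapping[str, Ligand]
    repressors: Mapping[str, RepressorSpec]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligands", dict(self.ligands))
        object.__setattr__(self, "repressors", dict(self.repressors))
        overlap = set(self.ligands) & set(self.repressors)
        if overlap:
            raise ValueError(f"names used for both ligand and repressor: {overlap}")
        for rep in self.repressors.values():
            if rep.cognate_ligand not in self.ligands:
                raise ValueError(
                    f"repressor {rep.name!r}: unknown cognate ligand "
                    f"{rep.cognate_ligand!r}"
                )

    @classmethod
    def from_lists(
        cls, ligands: Iterable[Ligand], repressors: Iterable[RepressorSpec]
    ) -> "SpeciesRegistry":
        return cls(
            ligands={l.name: l for l in ligands},
            repressors={r.name: r for r in repressors},
        )

    def ligand(self, name: str) -> Ligand:
        return self.ligands[name]

    def repressor(self, name: str) -> RepressorSpec:
        return self.repressors[name]

    def is_ligand(self, name: str) -> bool:
        return name in self.ligands

    def is_repressor(self, name: str) -> bool:
        return name in self.repressors


@dataclass(frozen=True)
class ReactionSystem:
    """Templates + constant species + input-signal mapping: one logic gate.

    ``input_map`` maps each input-signal name to the set of species (ligand
    and/or repressor names) supplied when that input is 1.  Ligands enter at
    their registry working concentrations.  A ligand may not be both an
    input-controlled species and a nonzero constant.
    """

    name: str
    templates: Sequence[CircularTemplate]
    constants: SpeciesState
    input_map: Mapping[str, frozenset]
    registry: SpeciesRegistry

    def __post_init__(self) -> None:
        object.__setattr__(self, "templates", tuple(self.templates))
        if not self.templates:
            raise ValueError(f"system {self.name!r}: at least one template required")
        imap = {k: frozenset(v) for k, v in self.input_map.items()}
        object.__setattr__(self, "input_map", imap)
        for rep in self.constants.repressors_present:
            if not self.registry.is_repressor(rep):
                raise ValueError(f"unknown constant repressor {rep!r}")
        for lig in self.constants.ligand_concentrations:
            if not self.registry.is_ligand(lig):
                raise ValueError(f"unknown constant ligand {lig!r}")
        for inp, species in imap.items():
            for s in species:
                if self.registry.is_ligand(s):
                    if self.constants.concentration(s) > 0:
                        raise ValueError(
                            f"ligand {s!r} is both a constant and controlled by "
                            f"input {inp!r}"
                        )
                elif not self.registry.is_repressor(s):
                    raise ValueError(
                        f"input {inp!r}: unknown species {s!r} (not a registered "
                        "ligand or repressor)"
                    )
        for tpl in self.templates:
            for site in tpl.sites:
                if not self.registry.is_repressor(site.cognate_repressor):
                    raise ValueError(
                        f"template {tpl.name!r}: site for unregistered repressor "
                        f"{site.cognate_repressor!r}"
                    )

    @property
    def input_names(self) -> tuple:
        return tuple(self.input_map)


def resolve_state(system: ReactionSystem, assignment: Mapping[str, int]) -> SpeciesState:
    """Merge the system's constants with the species of all inputs set to 1.

    ``assignment`` must cover exactly the system's input names.  Ligands
    supplied by an input enter at their working concentration (never lowering
    an existing constant concentration).
    """
    if set(assignment) != set(system.input_map):
        raise ValueError(
            f"assignment keys {sorted(assignment)} do not match inputs "
            f"{sorted(system.input_map)}"
        )
    reps = set(system.constants.repressors_present)
    ligs = dict(system.constants.ligand_concentrations)
    for inp, species in system.input_map.items():
        if not assignment[inp]:
            continue
        for s in species:
            if system.registry.is_repressor(s):
                reps.add(s)
            else:
                working = system.registry.ligand(s).working_concentration_mM
                ligs[s] = max(ligs.get(s, 0.0), working)
    return SpeciesState(frozenset(reps), ligs)


def site_occupied(
    site: OperatorSite, registry: SpeciesRegistry, state: SpeciesState
) -> int:
    """Whether a repressor sits on this operator site under ``state``.

    An absent repressor never binds.  A present inducer-regulated repressor
    binds unless some ligand at or above its threshold releases it; a present
    anti-inducer-regulated repressor binds only when some ligand at or above
    its threshold triggers binding.
    """
    rep = registry.repressor(site.cognate_repressor)
    if rep.name not in state.repressors_present:
        return 0
    switched = any(
        rep.is_switched_by(lig, conc)
        for lig, conc in state.ligand_concentrations.items()
    )
    if rep.mode is RegulationMode.INDUCER_REGULATED:
        return 0 if switched else 1
    return 1 if switched else 0


def occupied_sites(
    template: CircularTemplate, registry: SpeciesRegistry, state: SpeciesState
) -> list:
    """The subset of a template's sites currently bound by a repressor."""
    return [s for s in template.sites if site_occupied(s, registry, state)]


def template_active(
    template: CircularTemplate, registry: SpeciesRegistry, state: SpeciesState
) -> int:
    """1 iff every site on the circular template is unoccupied.

    Any bound site stops the polymerase on its way around the circle, so
    activity is the conjunction over sites of (1 - occupancy); site order and
    position never matter.
    """
    return int(
        all(not site_occupied(s, registry, state) for s in template.sites)
    )


def system_activity(
    system: ReactionSystem, assignment: Mapping[str, int]
) -> tuple:
    """(number of active templates, fraction of templates active).

    Templates are independent: a repressor bound on one circle does not
    affect another circle in the same reaction.
    """
    state = resolve_state(system, assignment)
    count = sum(
        template_active(t, system.registry, state) for t in system.templates
    )
    return count, count / len(system.templates)


def switch_matrix(
    registry: SpeciesRegistry,
    concentrations: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Ligand x repressor matrix of allosteric switching at given concentrations.

    Entry (L, R) is 1 if ligand L alone, at ``concentrations[L]`` (default:
    its working concentration), switches repressor R.  At the default working
    concentrations the matrix is diagonal — the orthogonality condition for
    running several modules in one reaction.
    """
    concentrations = dict(concentrations or {})
    lig_names = list(registry.ligands)
    rep_names = list(registry.repressors)
    data = []
    for lig in lig_names:
        conc = concentrations.get(
            lig, registry.ligand(lig).working_concentration_mM
        )
        data.append(
            [
                int(registry.repressor(rep).is_switched_by(lig, conc))
                for rep in rep_names
            ]
        )
    return pd.DataFrame(data, index=lig_names, columns=rep_names)
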
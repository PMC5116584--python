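"""The built-in catalogue of reference gate designs.

Seventeen designs ship with the package: the four basic modules (one
repressor-operator pair with its metabolite and the repressor itself as the
two inputs) and the thirteen constructed gates — twelve two-input gates plus
one three-input gate.  Each design is data (templates, constant species,
input mapping), not code, and is returned as a ready-to-evaluate
:class:`~rcalogic.core.ReactionSystem`.

Design vocabulary:

* series connection — several operator sites on one circular template;
  RCA runs only if every site is free (conjunction);
* parallel connection — several templates in one reaction; signal appears
  if any template runs (disjunction);
* composite input — one input signal supplying several species at once
  (e.g. the XOR gate's input A adds both IPTG and L-Trp).
"""

from __future__ import annotations

from typing import Optional

from .core import (
    CircularTemplate,
    OperatorSite,
    ReactionSystem,
    SpeciesRegistry,
    SpeciesState,
)
from .defaults import DEFAULT_OPERATOR_SEQUENCES, default_registry

__all__ = [
    "BASIC_MODULE_NAMES",
    "TWO_INPUT_GATE_NAMES",
    "GATE_NAMES_13",
    "CATALOGUE_NAMES",
    "catalogue_design",
]

BASIC_MODULE_NAMES = ("ORN1", "ORN2", "NAND1", "NAND2")
TWO_INPUT_GATE_NAMES = (
    "AND",
    "OR",
    "NOR",
    "NAND",
    "ANDN",
    "ORN",
    "XNOR",
    "XOR",
    "YES",
    "NOT",
    "ALL",
    "NONE",
)
GATE_NAMES_13 = TWO_INPUT_GATE_NAMES + ("THREE_INPUT",)
CATALOGUE_NAMES = BASIC_MODULE_NAMES + GATE_NAMES_13

# name -> (templates as lists of repressor names, constant repressors,
#          ordered inputs as (signal name, species supplied))
_DESIGNS = {
    # Basic modules: metabolite and repressor are themselves the two inputs.
    "ORN1": ([["LacI"]], [], [("IPTG", ["IPTG"]), ("LacI", ["LacI"])]),
    "ORN2": ([["GalR"]], [], [("D-Gal", ["D-Gal"]), ("GalR", ["GalR"])]),
    "NAND1": ([["TrpR"]], [], [("L-Trp", ["L-Trp"]), ("TrpR", ["TrpR"])]),
    "NAND2": ([["MetJ"]], [], [("SAM", ["SAM"]), ("MetJ", ["MetJ"])]),
    # Series / parallel combinations of two modules.
    "AND": (
        [["LacI", "GalR"]],
        ["LacI", "GalR"],
        [("IPTG", ["IPTG"]), ("D-Gal", ["D-Gal"])],
    ),
    "OR": (
        [["LacI"], ["GalR"]],
        ["LacI", "GalR"],
        [("IPTG", ["IPTG"]), ("D-Gal", ["D-Gal"])],
    ),
    "NOR": (
        [["MetJ", "TrpR"]],
        ["MetJ", "TrpR"],
        [("SAM", ["SAM"]), ("L-Trp", ["L-Trp"])],
    ),
    "NAND": (
        [["MetJ"], ["TrpR"]],
        ["MetJ", "TrpR"],
        [("SAM", ["SAM"]), ("L-Trp", ["L-Trp"])],
    ),
    "ANDN": (
        [["GalR", "TrpR"]],
        ["GalR", "TrpR"],
        [("D-Gal", ["D-Gal"]), ("L-Trp", ["L-Trp"])],
    ),
    "ORN": (
        [["GalR"], ["TrpR"]],
        ["GalR", "TrpR"],
        [("D-Gal", ["D-Gal"]), ("L-Trp", ["L-Trp"])],
    ),
    # Flexible combinations with composite inputs.
    "XNOR": (
        [["LacI", "GalR"]],
        [],
        [("A", ["GalR", "IPTG"]), ("B", ["LacI", "D-Gal"])],
    ),
    "XOR": (
        [["LacI", "MetJ"], ["GalR", "TrpR"]],
        ["LacI", "GalR", "MetJ", "TrpR"],
        [("A", ["IPTG", "L-Trp"]), ("B", ["D-Gal", "SAM"])],
    ),
    "YES": (
        [["LacI", "GalR"]],
        ["GalR"],
        [("IPTG", ["IPTG"]), ("D-Gal", ["D-Gal"])],
    ),
    "NOT": (
        [["MetJ", "TrpR"]],
        ["TrpR"],
        [("SAM", ["SAM"]), ("L-Trp", ["L-Trp"])],
    ),
    "ALL": (
        [["LacI", "GalR"]],
        [],
        [("IPTG", ["IPTG"]), ("D-Gal", ["D-Gal"])],
    ),
    # GalR stays bound whatever the inputs do: its inducer is never supplied.
    "NONE": (
        [["LacI", "GalR"]],
        ["GalR"],
        [("IPTG", ["IPTG"]), ("LacI", ["LacI"])],
    ),
    # Three modules in series on a single circle.
    "THREE_INPUT": (
        [["LacI", "GalR", "TrpR"]],
        ["LacI", "GalR", "TrpR"],
        [("IPTG", ["IPTG"]), ("D-Gal", ["D-Gal"]), ("L-Trp", ["L-Trp"])],
    ),
}


def _site_for(repressor: str, registry: SpeciesRegistry) -> OperatorSite:
    spec = registry.repressor(repressor)
    seq = DEFAULT_OPERATOR_SEQUENCES.get(spec.operator_id, (None,))[0]
    return OperatorSite(
        operator_id=spec.operator_id, cognate_repressor=repressor, sequence=seq
    )


def catalogue_design(
    name: str, registry: Optional[SpeciesRegistry] = None
) -> ReactionSystem:
    """Return the reference design for one of the 17 catalogue entries.

    Raises ``KeyError`` with the list of valid names for unknown gates.
    """
    if name not in _DESIGNS:
        raise KeyError(
            f"unknown catalogue gate {name!r}; valid names: {', '.join(CATALOGUE_NAMES)}"
        )
    registry = registry or default_registry()
    template_reps, constant_reps, inputs = _DESIGNS[name]
    templates = [
        CircularTemplate(
            name=f"{name}-T{i + 1}",
            sites=[_site_for(rep, registry) for rep in reps],
        )
        for i, reps in enumerate(template_reps)
    ]
    return ReactionSystem(
        name=name,
        templates=templates,
        constants=SpeciesState(frozenset(constant_reps), {}),
        input_map={sig: frozenset(species) for sig, species in inputs},
        registry=registry,
    )
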
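"""Default species registry and operator sequences.

The shipped repertoire is the two-pairs model system used throughout the
package: two inducer-regulated repressors (LacI released by IPTG, GalR by
D-galactose) and two anti-inducer-regulated repressors (TrpR armed by
L-tryptophan, MetJ by S-adenosylmethionine).

Working concentrations encode the orthogonality conditions of the system:
D-galactose is used at 5 mM because higher concentrations weakly induce
LacI (cross-threshold 10 mM here), and SAM at 1 mM because higher
concentrations arm TrpR (cross-threshold 1.5 mM here).  MetJ represses RCA
less tightly than the other three repressors, which is captured as a leak
fraction of 0.15 consumed by the kinetics layer only.

The operator sequences shipped here are replaceable placeholders taken from
canonical literature motifs (lacO1, gal O_E, trpO, a tandem met-box); swap
in project-specific sequences through :class:`rcalogic.seqdesign.OperatorDB`
or a design document's ``operators`` section.
"""

from __future__ import annotations

from .core import Ligand, RegulationMode, RepressorSpec, SpeciesRegistry

__all__ = [
    "default_registry",
    "DEFAULT_OPERATOR_SEQUENCES",
    "REPRESSOR_AMOUNTS_PMOL",
    "TEMPLATE_AMOUNT_PMOL",
]

# Canonical motif placeholders (uppercase ACGT); replace with the sequences
# actually synthesised for a given experiment.
DEFAULT_OPERATOR_SEQUENCES = {
    "lacO1": ("AATTGTGAGCGGATAACAATT", "LacI"),
    "galO": ("GTGTAAACGATTCCAC", "GalR"),
    "trpO": ("TGTACTAGTTAACTAGTACA", "TrpR"),
    "metO": ("AGACGTCTAGACGTCT", "MetJ"),
}

# Reaction-setup metadata only: stoichiometric excess of repressor over
# template (>= 100x) is assumed by the Boolean layer.
REPRESSOR_AMOUNTS_PMOL = {"LacI": 5.0, "GalR": 10.0, "MetJ": 5.0, "TrpR": 10.0}
TEMPLATE_AMOUNT_PMOL = 0.05


def default_registry() -> SpeciesRegistry:
    """The two-pairs repertoire with its working concentrations and thresholds."""
    ligands = [
        Ligand("IPTG", working_concentration_mM=5.0),
        Ligand("D-Gal", working_concentration_mM=5.0),
        Ligand("SAM", working_concentration_mM=1.0),
        Ligand("L-Trp", working_concentration_mM=1.0),
    ]
    repressors = [
        RepressorSpec(
            name="LacI",
            mode=RegulationMode.INDUCER_REGULATED,
            cognate_ligand="IPTG",
            operator_id="lacO1",
            # D-Gal weakly induces LacI only above its cross-threshold,
            # strictly above the 5 mM working concentration.
            affinity_thresholds={"IPTG": 0.5, "D-Gal": 10.0},
            leak=0.0,
        ),
        RepressorSpec(
            name="GalR",
            mode=RegulationMode.INDUCER_REGULATED,
            cognate_ligand="D-Gal",
            operator_id="galO",
            affinity_thresholds={"D-Gal": 0.5},
            leak=0.0,
        ),
        RepressorSpec(
            name="TrpR",
            mode=RegulationMode.ANTI_INDUCER_REGULATED,
            cognate_ligand="L-Trp",
            operator_id="trpO",
            # High SAM arms TrpR; the 1 mM working concentration stays below
            # the 1.5 mM cross-threshold.
            affinity_thresholds={"L-Trp": 0.5, "SAM": 1.5},
            leak=0.0,
        ),
        RepressorSpec(
            name="MetJ",
            mode=RegulationMode.ANTI_INDUCER_REGULATED,
            cognate_ligand="SAM",
            operator_id="metO",
            affinity_thresholds={"SAM": 0.5},
            leak=0.15,  # MetJ suppresses RCA less tightly than the others
        ),
    ]
    return SpeciesRegistry.from_lists(ligands, repressors)
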
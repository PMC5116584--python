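"""Structured-text design documents: schema, reader, writer.

A design document is a YAML file describing one reaction system: the
species registry (omitted sections fall back to the shipped defaults), the
templates with their operator sites, the constant species, and the
input-signal mapping.  Documents are schema-validated (unknown keys are
rejected with the path to the offending field) and round-trip losslessly
through :func:`save_design` / :func:`load_design`.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .core import (
    CircularTemplate,
    Ligand,
    OperatorSite,
    ReactionSystem,
    RegulationMode,
    RepressorSpec,
    SpeciesRegistry,
    SpeciesState,
)
from .defaults import DEFAULT_OPERATOR_SEQUENCES, default_registry

__all__ = [
    "SCHEMA_VERSION",
    "DesignDocumentError",
    "load_design",
    "loads_design",
    "save_design",
    "dumps_design",
]

SCHEMA_VERSION = 1


class DesignDocumentError(ValueError):
    """Schema violation with a path-to-field diagnostic."""


class _LigandModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    working_concentration_mM: float = 1.0


class _RepressorModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    mode: RegulationMode
    cognate_ligand: str
    operator_id: str
    affinity_thresholds: Dict[str, float]
    leak: float = 0.0


class _SiteModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    repressor: str
    operator_id: Optional[str] = None


class _TemplateModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    sites: List[_SiteModel] = Field(default_factory=list)
    spacers: Optional[List[int]] = None
    primer_region: str = ""
    total_length: Optional[int] = None


class _ConstantsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    repressors: List[str] = Field(default_factory=list)
    ligands: Dict[str, float] = Field(default_factory=dict)


class _DocumentModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: int = SCHEMA_VERSION
    name: str
    ligands: Optional[List[_LigandModel]] = None
    repressors: Optional[List[_RepressorModel]] = None
    operators: Dict[str, str] = Field(default_factory=dict)
    templates: List[_TemplateModel]
    constants: _ConstantsModel = Field(default_factory=_ConstantsModel)
    input_map: Dict[str, List[str]]
    metadata: Dict[str, str] = Field(default_factory=dict)


def _registry_from_doc(doc: _DocumentModel) -> SpeciesRegistry:
    if doc.ligands is None and doc.repressors is None:
        return default_registry()
    base = default_registry()
    ligands = (
        {l.name: Ligand(l.name, l.working_concentration_mM) for l in doc.ligands}
        if doc.ligands is not None
        else dict(base.ligands)
    )
    repressors = (
        {
            r.name: RepressorSpec(
                name=r.name,
                mode=r.mode,
                cognate_ligand=r.cognate_ligand,
                operator_id=r.operator_id,
                affinity_thresholds=r.affinity_thresholds,
                leak=r.leak,
            )
            for r in doc.repressors
        }
        if doc.repressors is not None
        else dict(base.repressors)
    )
    return SpeciesRegistry(ligands=ligands, repressors=repressors)


def _doc_to_system(doc: _DocumentModel) -> ReactionSystem:
    registry = _registry_from_doc(doc)
    operator_seqs = dict(doc.operators)

    def sequence_for(operator_id: str) -> Optional[str]:
        if operator_id in operator_seqs:
            return operator_seqs[operator_id]
        default = DEFAULT_OPERATOR_SEQUENCES.get(operator_id)
        return default[0] if default else None

    templates = []
    for tpl in doc.templates:
        sites = []
        for site in tpl.sites:
            rep = registry.repressor(site.repressor)
            op_id = site.operator_id or rep.operator_id
            sites.append(
                OperatorSite(
                    operator_id=op_id,
                    cognate_repressor=site.repressor,
                    sequence=sequence_for(op_id),
                )
            )
        templates.append(
            CircularTemplate(
                name=tpl.name,
                sites=sites,
                spacers=tuple(tpl.spacers) if tpl.spacers else (),
                primer_region=tpl.primer_region,
                total_length=tpl.total_length,
            )
        )
    return ReactionSystem(
        name=doc.name,
        templates=templates,
        constants=SpeciesState(
            frozenset(doc.constants.repressors), doc.constants.ligands
        ),
        input_map={k: frozenset(v) for k, v in doc.input_map.items()},
        registry=registry,
    )


def _format_error(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        path = ".".join(str(p) for p in err["loc"]) or "<document>"
        lines.append(f"{path}: {err['msg']}")
    return "; ".join(lines)


def loads_design(text: str) -> ReactionSystem:
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise DesignDocumentError("document root must be a mapping")
    if raw.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise DesignDocumentError(
            f"schema_version: unsupported version {raw.get('schema_version')!r}"
        )
    try:
        doc = _DocumentModel.model_validate(raw)
    except ValidationError as exc:
        raise DesignDocumentError(_format_error(exc)) from exc
    try:
        return _doc_to_system(doc)
    except (KeyError, ValueError) as exc:
        raise DesignDocumentError(str(exc)) from exc


def load_design(path) -> ReactionSystem:
    with open(path, "r", encoding="utf-8") as handle:
        return loads_design(handle.read())


def dumps_design(system: ReactionSystem) -> str:
    registry = system.registry
    operators = {}
    for tpl in system.templates:
        for site in tpl.sites:
            if site.sequence is not None:
                operators[site.operator_id] = site.sequence
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": system.name,
        "ligands": [
            {
                "name": l.name,
                "working_concentration_mM": l.working_concentration_mM,
            }
            for l in registry.ligands.values()
        ],
        "repressors": [
            {
                "name": r.name,
                "mode": r.mode.value,
                "cognate_ligand": r.cognate_ligand,
                "operator_id": r.operator_id,
                "affinity_thresholds": dict(r.affinity_thresholds),
                "leak": r.leak,
            }
            for r in registry.repressors.values()
        ],
        "operators": operators,
        "templates": [
            {
                "name": tpl.name,
                "sites": [
                    {
                        "repressor": s.cognate_repressor,
                        "operator_id": s.operator_id,
                    }
                    for s in tpl.sites
                ],
                "spacers": list(tpl.spacers),
                "primer_region": tpl.primer_region,
                "total_length": tpl.total_length,
            }
            for tpl in system.templates
        ],
        "constants": {
            "repressors": sorted(system.constants.repressors_present),
            "ligands": dict(system.constants.ligand_concentrations),
        },
        "input_map": {k: sorted(v) for k, v in system.input_map.items()},
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def save_design(system: ReactionSystem, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(dumps_design(system))
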
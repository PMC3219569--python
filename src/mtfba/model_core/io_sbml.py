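"""SBML read/write, backed by COBRApy's battle-tested SBML layer.

COBRApy transparently handles both SBML Level 3 with the ``fbc`` flux
bounds extension and legacy Level 2 files with bounds in kinetic-law
parameters (the dialect of 2011-era SimPheny/COBRA exports); writing
always emits Level 3 + fbc.

Bracketed ids such as ``glc[h_c]`` are not valid SBML SIds, so species
and reactions are written under sanitized ids with the original id
preserved in the SBML notes (key ``original_id``), together with the
reaction ``kind`` flag and ``subsystem``.  Files written by other tools
lack these notes and fall back to id/compartment reconstruction plus
kind heuristics.
"""

from __future__ import annotations

import re
from pathlib import Path

import cobra

from .gpr import parse_gpr
from .types import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
    make_met_id,
    split_met_id,
)

_INVALID_SID = re.compile(r"[^A-Za-z0-9_]")


class SBMLFormatError(ValueError):
    """Raised when an SBML file cannot be read as a metabolic model."""


def _sanitize(identifier: str) -> str:
    sid = _INVALID_SID.sub("_", identifier)
    if not sid or sid[0].isdigit():
        sid = "x" + sid
    return sid


def _unique(sid: str, taken: set[str]) -> str:
    candidate = sid
    k = 1
    while candidate in taken:
        k += 1
        candidate = f"{sid}_{k}"
    taken.add(candidate)
    return candidate


def to_cobra(model: MetabolicModel) -> cobra.Model:
    """Convert to a cobra.Model with sanitized ids and provenance notes."""
    cmodel = cobra.Model(_sanitize(model.id), name=model.name)
    met_map: dict[str, cobra.Metabolite] = {}
    taken: set[str] = set()
    for met in model.metabolites.values():
        cmet = cobra.Metabolite(
            _unique(_sanitize(f"{met.base_id}_{met.compartment}"), taken),
            name=met.name or met.id,
            compartment=_sanitize(met.compartment),
            formula=met.formula,
            charge=met.charge,
        )
        cmet.notes = {"original_id": met.id}
        met_map[met.id] = cmet
    cmodel.add_metabolites(list(met_map.values()))

    bad_genes = [g for g in model.genes if _sanitize(g) != g]
    if bad_genes:
        raise SBMLFormatError(
            f"gene ids {bad_genes} are not valid SBML SIds; rename genes "
            "before writing SBML (the table format has no such restriction)"
        )

    rxn_taken: set[str] = set()
    crxns = []
    for rxn in model.reactions.values():
        crxn = cobra.Reaction(
            _unique(_sanitize(rxn.id), rxn_taken),
            name=rxn.name or rxn.id,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        crxn.add_metabolites(
            {met_map[met_id]: coef for met_id, coef in rxn.stoichiometry.items()}
        )
        crxn.gene_reaction_rule = rxn.gpr.to_string()
        crxn.subsystem = rxn.subsystem
        crxn.notes = {
            "original_id": rxn.id,
            "kind": rxn.kind.value,
            "subsystem": rxn.subsystem,
        }
        crxns.append(crxn)
    cmodel.add_reactions(crxns)
    for rxn in crxns:
        orig = rxn.notes["original_id"]
        coef = model.objective.get(orig, 0.0)
        if coef:
            rxn.objective_coefficient = coef
    return cmodel


def _infer_kind(crxn: cobra.Reaction) -> ReactionKind:
    label = f"{crxn.id} {crxn.name}".lower()
    if len(crxn.metabolites) == 1:
        if "biomass" in label:
            return ReactionKind.BIOMASS
        return ReactionKind.EXCHANGE
    if "biomass" in label:
        return ReactionKind.BIOMASS
    compartments = {m.compartment for m in crxn.metabolites}
    if len(compartments) > 1:
        return ReactionKind.TRANSPORTER
    return ReactionKind.INTERNAL


def _original_met_id(cmet: cobra.Metabolite) -> str:
    notes = cmet.notes or {}
    if "original_id" in notes:
        return str(notes["original_id"])
    comp = cmet.compartment or "c"
    base = cmet.id
    # legacy COBRA convention: id carries a trailing compartment suffix
    if base.endswith(f"_{comp}"):
        base = base[: -(len(comp) + 1)]
    elif base.endswith(f"[{comp}]"):
        base = base[: -(len(comp) + 2)]
    return make_met_id(base, comp)


def from_cobra(cmodel: cobra.Model, model_id: str | None = None) -> MetabolicModel:
    """Convert a cobra.Model into a MetabolicModel."""
    model = MetabolicModel(model_id or cmodel.id or "model", cmodel.name or "")
    met_ids: dict[str, str] = {}
    for cmet in cmodel.metabolites:
        mid = _original_met_id(cmet)
        if mid in met_ids.values():  # pragma: no cover - defensive
            mid = make_met_id(cmet.id, cmet.compartment or "c")
        met_ids[cmet.id] = mid
        base, comp = split_met_id(mid)
        model.add_metabolite(
            Metabolite(
                id=mid,
                base_id=base,
                compartment=comp,
                name=cmet.name or "",
                formula=cmet.formula or None,
                charge=cmet.charge,
            )
        )
    objective = cobra.util.solver.linear_reaction_coefficients(cmodel)
    obj_map = {rxn.id: coef for rxn, coef in objective.items()}
    final_objective: dict[str, float] = {}
    for crxn in cmodel.reactions:
        notes = crxn.notes or {}
        rid = str(notes.get("original_id", crxn.id))
        kind = (
            ReactionKind(str(notes["kind"]))
            if "kind" in notes
            else _infer_kind(crxn)
        )
        subsystem = str(notes.get("subsystem", crxn.subsystem or ""))
        rxn = Reaction(
            id=rid,
            stoichiometry={
                met_ids[cmet.id]: coef for cmet, coef in crxn.metabolites.items()
            },
            lower_bound=crxn.lower_bound,
            upper_bound=crxn.upper_bound,
            gpr=parse_gpr(crxn.gene_reaction_rule),
            subsystem=subsystem,
            kind=kind,
            name=crxn.name or "",
        )
        model.add_reaction(rxn)
        if crxn.id in obj_map:
            final_objective[rid] = obj_map[crxn.id]
    model.set_objective(final_objective)
    model.validate()
    return model


def save_sbml(model: MetabolicModel, path: str | Path) -> None:
    cobra.io.write_sbml_model(to_cobra(model), str(path))


def load_sbml(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise SBMLFormatError(f"cannot read SBML file {path}: {exc}") from exc
    return from_cobra(cmodel, model_id)
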
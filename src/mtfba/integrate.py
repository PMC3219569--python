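"""Multi-tissue model assembly.

Tissue models are tagged (every metabolite, reaction and compartment id
carries the tissue tag), merged through a shared blood compartment
``bl`` that also represents interstitial fluid and urine, equipped with
a bicarbonate buffer for proton balancing, and rescaled from
per-gram-dry-weight to whole-body flux units.

Sign convention for blood exchanges: negative flux is uptake into the
blood from the extra-system, positive flux is secretion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .model_core import (
    MetabolicModel,
    Metabolite,
    ModelConsistencyError,
    Reaction,
    ReactionKind,
    make_met_id,
    split_met_id,
)

BLOOD = "bl"
EXTRACELLULAR = "e"

#: (formula, charge) of the bicarbonate buffer participants.
_BUFFER_SPECIES = {
    "co2": ("CO2", 0),
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "hco3": ("CHO3", -1),
}


class IntegrationError(ModelConsistencyError):
    """Raised when tagging or merging cannot produce a consistent model."""


@dataclass
class MassParams:
    """Whole-tissue scaling parameters.

    ``wet_mass_g`` is the tissue wet mass, ``cell_fraction`` the mass
    fraction contributed by the modeled cell type (e.g. 0.8 for
    hepatocytes in liver), ``water_fraction`` the tissue water content,
    and ``growth_rate_per_h`` the in-vitro growth rate used as the
    biomass maintenance lower bound.
    """

    wet_mass_g: float
    cell_fraction: float
    water_fraction: float
    growth_rate_per_h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.cell_fraction <= 1.0:
            raise ValueError("cell_fraction must lie in [0, 1]")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water_fraction must lie in [0, 1]")
        if self.wet_mass_g < 0:
            raise ValueError("wet_mass_g must be nonnegative")

    @property
    def dry_cell_mass_g(self) -> float:
        return self.wet_mass_g * self.cell_fraction * (1.0 - self.water_fraction)


@dataclass
class TissueModel:
    """A tagged tissue model ready for merging."""

    model: MetabolicModel
    tissue_tag: str
    biomass_reaction_id: str | None = None
    mass_params: MassParams | None = None
    provenance: dict[str, str] = field(default_factory=dict)  # tagged -> original id
    rescaled: bool = False

    def __post_init__(self) -> None:
        if self.biomass_reaction_id is not None:
            rxn = self.model.reactions.get(self.biomass_reaction_id)
            if rxn is None:
                raise IntegrationError(
                    f"biomass reaction {self.biomass_reaction_id!r} not in model"
                )
            if rxn.kind is not ReactionKind.BIOMASS:
                raise IntegrationError(
                    f"reaction {self.biomass_reaction_id!r} is not kind=biomass"
                )

    @property
    def extracellular_compartment(self) -> str:
        return f"{self.tissue_tag}_{EXTRACELLULAR}"


@dataclass
class MultiTissueModel:
    """Tissue models joined through a blood compartment.

    ``provenance`` maps every reaction id to ``(tissue_tag, original_id)``;
    reactions created during merging map to ``("bl", "created")``.
    """

    model: MetabolicModel
    provenance: dict[str, tuple[str, str]]
    tissue_tags: list[str]
    buffer_reaction_ids: list[str] = field(default_factory=list)
    blood_exchange_ids: list[str] = field(default_factory=list)
    tissues: dict[str, TissueModel] = field(default_factory=dict)

    def validate(self) -> None:
        self.model.validate()
        for rid in self.model.reactions:
            if rid not in self.provenance:
                raise IntegrationError(f"reaction {rid!r} missing from provenance")
        blood_mets: set[str] = set()
        for rxn in self.model.reactions.values():
            mets = {
                mid: self.model.metabolites[mid].compartment
                for mid in rxn.stoichiometry
            }
            if rxn.kind is ReactionKind.EXCHANGE and any(
                comp != BLOOD for comp in mets.values()
            ):
                raise IntegrationError(
                    f"exchange reaction {rxn.id!r} touches a non-blood metabolite"
                )
            if rxn.kind in (ReactionKind.TRANSPORTER, ReactionKind.EXCHANGE,
                            ReactionKind.BUFFER):
                blood_mets |= {m for m, comp in mets.items() if comp == BLOOD}
        for met in self.model.metabolites.values():
            if met.compartment == BLOOD and met.id not in blood_mets:
                raise IntegrationError(
                    f"blood metabolite {met.id!r} participates in no "
                    "transporter or exchange"
                )

    def reactions_of_tissue(self, tag: str) -> list[str]:
        return [rid for rid, (t, _) in self.provenance.items() if t == tag]

    def deactivated(self, tags: Iterable[str]) -> "MultiTissueModel":
        """Copy with all reactions of the given tissues bounded to zero.

        Used for individual-tissue simulations inside the merged model.
        """
        tags = set(tags)
        unknown = tags - set(self.tissue_tags)
        if unknown:
            raise IntegrationError(f"unknown tissue tag(s) {sorted(unknown)}")
        new_model = self.model.copy()
        for rid, (tissue, _) in self.provenance.items():
            if tissue in tags:
                new_model.reactions[rid].bounds = (0.0, 0.0)
        return replace(self, model=new_model, provenance=dict(self.provenance))

    def copy(self) -> "MultiTissueModel":
        return replace(
            self,
            model=self.model.copy(),
            provenance=dict(self.provenance),
            tissue_tags=list(self.tissue_tags),
            buffer_reaction_ids=list(self.buffer_reaction_ids),
            blood_exchange_ids=list(self.blood_exchange_ids),
        )


def _tag_met_id(met_id: str, tag: str) -> str:
    base, comp = split_met_id(met_id)
    return make_met_id(base, f"{tag}_{comp}")


def tag_model(
    model: MetabolicModel,
    tissue_tag: str,
    biomass_reaction_id: str | None = None,
    mass_params: MassParams | None = None,
) -> TissueModel:
    """Annotate every metabolite, reaction, and compartment with a tissue tag.

    ``glc[c]`` tagged ``h`` becomes ``glc[h_c]``, reaction ``PGI`` becomes
    ``PGI[h]``.  Extracellular species end up in compartment
    ``<tag>_e`` and are later identified with blood species during
    merging.
    """
    if not tissue_tag or "_" in tissue_tag or "[" in tissue_tag:
        raise IntegrationError(f"invalid tissue tag {tissue_tag!r}")
    prefix = f"{tissue_tag}_"
    if any(c == tissue_tag or c.startswith(prefix) for c in model.compartments):
        raise IntegrationError(
            f"model already carries compartments tagged {tissue_tag!r}"
        )
    tagged = MetabolicModel(f"{model.id}[{tissue_tag}]", model.name)
    for met in model.metabolites.values():
        tagged.add_metabolite(
            Metabolite(
                id=_tag_met_id(met.id, tissue_tag),
                base_id=met.base_id,
                compartment=f"{tissue_tag}_{met.compartment}",
                name=met.name,
                formula=met.formula,
                charge=met.charge,
            )
        )
    provenance: dict[str, str] = {}
    objective: dict[str, float] = {}
    for rxn in model.reactions.values():
        new_id = f"{rxn.id}[{tissue_tag}]"
        new = Reaction(
            id=new_id,
            stoichiometry={
                _tag_met_id(mid, tissue_tag): coef
                for mid, coef in rxn.stoichiometry.items()
            },
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
            gpr=rxn.gpr,
            subsystem=rxn.subsystem,
            kind=rxn.kind,
            name=rxn.name,
        )
        tagged.add_reaction(new)
        provenance[new_id] = rxn.id
        if rxn.id in model.objective:
            objective[new_id] = model.objective[rxn.id]
    tagged.set_objective(objective)

    biomass_id = None
    if biomass_reaction_id is not None:
        biomass_id = f"{biomass_reaction_id}[{tissue_tag}]"
    else:
        candidates = [
            rid
            for rid, rxn in tagged.reactions.items()
            if rxn.kind is ReactionKind.BIOMASS
        ]
        if len(candidates) == 1:
            biomass_id = candidates[0]
    return TissueModel(
        model=tagged,
        tissue_tag=tissue_tag,
        biomass_reaction_id=biomass_id,
        mass_params=mass_params,
        provenance=provenance,
    )


def merge_models(
    tissues: Sequence[TissueModel],
    blood_exchange_whitelist: Iterable[str],
    exchange_bound: float = 1000.0,
) -> MultiTissueModel:
    """Merge tagged tissue models through a new blood compartment.

    Each tissue's extracellular species (compartment ``<tag>_e``) is
    identified with the blood species of the same base id.  Tissue-level
    exchange reactions are deleted; one blood exchange per whitelisted
    base id is created.  Merge order is deterministic (tissues sorted by
    tag, reactions by id).
    """
    if len(tissues) < 2:
        raise IntegrationError("need at least two tissue models to merge")
    tags = [t.tissue_tag for t in tissues]
    if len(set(tags)) != len(tags):
        raise IntegrationError(f"duplicate tissue tags in merge set: {tags}")
    ordered = sorted(tissues, key=lambda t: t.tissue_tag)
    whitelist = sorted(set(blood_exchange_whitelist))

    merged = MetabolicModel("multi_tissue")
    provenance: dict[str, tuple[str, str]] = {}
    objective: dict[str, float] = {}

    def blood_met(base_id: str, template: Metabolite | None) -> str:
        mid = make_met_id(base_id, BLOOD)
        if mid not in merged.metabolites:
            merged.add_metabolite(
                Metabolite(
                    id=mid,
                    base_id=base_id,
                    compartment=BLOOD,
                    name=template.name if template else base_id,
                    formula=template.formula if template else None,
                    charge=template.charge if template else None,
                )
            )
        return mid

    for tissue in ordered:
        ec = tissue.extracellular_compartment
        met_map: dict[str, str] = {}
        for met in tissue.model.metabolites.values():
            if met.compartment == ec:
                met_map[met.id] = blood_met(met.base_id, met)
            else:
                met_map[met.id] = met.id
                if met.id not in merged.metabolites:
                    merged.add_metabolite(met.copy())
        for rid in sorted(tissue.model.reactions):
            rxn = tissue.model.reactions[rid]
            if rxn.kind is ReactionKind.EXCHANGE:
                continue  # tissue exchanges are removed; blood takes over
            new = rxn.copy()
            new.stoichiometry = {
                met_map[mid]: coef for mid, coef in rxn.stoichiometry.items()
            }
            merged.add_reaction(new)
            provenance[new.id] = (tissue.tissue_tag, tissue.provenance.get(rid, rid))
            if rid in tissue.model.objective:
                objective[new.id] = tissue.model.objective[rid]

    blood_exchange_ids: list[str] = []
    for base_id in whitelist:
        mid = make_met_id(base_id, BLOOD)
        if mid not in merged.metabolites:
            raise IntegrationError(
                f"whitelisted blood metabolite {base_id!r} does not occur in "
                "any tissue's extracellular space; its exchange would dangle"
            )
        ex_id = f"EX_{base_id}[{BLOOD}]"
        merged.add_reaction(
            Reaction(
                id=ex_id,
                stoichiometry={mid: -1.0},
                lower_bound=-exchange_bound,
                upper_bound=exchange_bound,
                kind=ReactionKind.EXCHANGE,
                name=f"{base_id} exchange (blood/extra-system)",
            )
        )
        provenance[ex_id] = (BLOOD, "created")
        blood_exchange_ids.append(ex_id)

    merged.set_objective(objective)
    merged.prune_unused_metabolites()
    mt = MultiTissueModel(
        model=merged,
        provenance=provenance,
        tissue_tags=sorted(tags),
        blood_exchange_ids=blood_exchange_ids,
        tissues={t.tissue_tag: t for t in ordered},
    )
    mt.validate()
    return mt


BUFFER_REACTION_ID = f"HCO3_BUFFER[{BLOOD}]"


def add_buffer(
    mt: MultiTissueModel,
    species: Mapping[str, str] | None = None,
    exchange_bound: float = 1000.0,
) -> MultiTissueModel:
    """Add the blood bicarbonate buffer ``co2 + h2o <-> h + hco3``.

    Creates the participating blood species when absent, plus exchange
    reactions for co2 and hco3 so the buffer can run in either direction.
    Idempotent: a model already containing the buffer is returned
    unchanged (as a copy).
    """
    names = dict(species or {k: k for k in _BUFFER_SPECIES})
    mt = mt.copy()
    model = mt.model
    if BUFFER_REACTION_ID in model.reactions:
        return mt

    met_ids: dict[str, str] = {}
    for role, (formula, charge) in _BUFFER_SPECIES.items():
        base = names.get(role, role)
        mid = make_met_id(base, BLOOD)
        if mid not in model.metabolites:
            model.add_metabolite(
                Metabolite(
                    id=mid, base_id=base, compartment=BLOOD,
                    formula=formula, charge=charge, name=base,
                )
            )
        met_ids[role] = mid

    buffer_rxn = Reaction(
        id=BUFFER_REACTION_ID,
        stoichiometry={
            met_ids["co2"]: -1.0,
            met_ids["h2o"]: -1.0,
            met_ids["h"]: 1.0,
            met_ids["hco3"]: 1.0,
        },
        lower_bound=-exchange_bound,
        upper_bound=exchange_bound,
        kind=ReactionKind.BUFFER,
        name="bicarbonate buffer (carbonic acid hydration couple)",
    )
    model.add_reaction(buffer_rxn)
    mt.provenance[BUFFER_REACTION_ID] = (BLOOD, "created")
    mt.buffer_reaction_ids = list(mt.buffer_reaction_ids) + [BUFFER_REACTION_ID]

    for role in ("co2", "hco3"):
        base = names.get(role, role)
        ex_id = f"EX_{base}[{BLOOD}]"
        if ex_id not in model.reactions:
            model.add_reaction(
                Reaction(
                    id=ex_id,
                    stoichiometry={met_ids[role]: -1.0},
                    lower_bound=-exchange_bound,
                    upper_bound=exchange_bound,
                    kind=ReactionKind.EXCHANGE,
                    name=f"{base} exchange (blood/extra-system)",
                )
            )
            mt.provenance[ex_id] = (BLOOD, "created")
            mt.blood_exchange_ids = list(mt.blood_exchange_ids) + [ex_id]
    mt.validate()
    return mt


def rescale_biomass(tissue: TissueModel) -> TissueModel:
    """Rescale a tissue's biomass function to whole-body units (mmol/h/body).

    The biomass stoichiometric coefficients (mmol/gDW) are multiplied by
    the tissue dry cell mass so that a biomass flux of 1/h drains the
    maintenance requirement of the whole tissue; the biomass lower bound
    is then set to the in-vitro growth rate.
    """
    if tissue.mass_params is None:
        raise IntegrationError(
            f"tissue {tissue.tissue_tag!r}: mass_params required for rescaling"
        )
    if tissue.rescaled:
        raise IntegrationError(
            f"tissue {tissue.tissue_tag!r} has already been rescaled"
        )
    if tissue.biomass_reaction_id is None:
        raise IntegrationError(
            f"tissue {tissue.tissue_tag!r}: no biomass reaction designated"
        )
    dry_mass = tissue.mass_params.dry_cell_mass_g
    if dry_mass <= 0:
        raise IntegrationError(
            f"tissue {tissue.tissue_tag!r}: degenerate dry cell mass "
            f"{dry_mass} g (check wet mass / fractions)"
        )
    model = tissue.model.copy()
    biomass = model.reactions[tissue.biomass_reaction_id]
    biomass.stoichiometry = {
        mid: coef * dry_mass for mid, coef in biomass.stoichiometry.items()
    }
    growth = tissue.mass_params.growth_rate_per_h
    biomass.bounds = (growth, max(biomass.upper_bound, growth))
    return replace(tissue, model=model, rescaled=True)


def wrap_multitissue(model: MetabolicModel) -> MultiTissueModel:
    """Rebuild a MultiTissueModel around a merged model loaded from disk.

    Provenance is reconstructed from the id convention: reactions named
    ``NAME[tag]`` belong to tissue ``tag``; everything else (blood
    exchanges, the buffer) is blood-created.
    """
    provenance: dict[str, tuple[str, str]] = {}
    tags: set[str] = set()
    buffer_ids: list[str] = []
    exchange_ids: list[str] = []
    for rid, rxn in model.reactions.items():
        base, _, rest = rid.rpartition("[")
        tag = rest[:-1] if rest.endswith("]") else ""
        if base and tag and tag != BLOOD:
            provenance[rid] = (tag, base)
            tags.add(tag)
        else:
            provenance[rid] = (BLOOD, "created")
        if rxn.kind is ReactionKind.BUFFER:
            buffer_ids.append(rid)
        elif rxn.kind is ReactionKind.EXCHANGE:
            exchange_ids.append(rid)
    mt = MultiTissueModel(
        model=model,
        provenance=provenance,
        tissue_tags=sorted(tags),
        buffer_reaction_ids=buffer_ids,
        blood_exchange_ids=exchange_ids,
    )
    mt.validate()
    return mt


def provenance_lookup(mt: MultiTissueModel, reaction_id: str) -> tuple[str, str]:
    """Origin of a merged reaction: ``(tissue_tag, original_id)``."""
    try:
        return mt.provenance[reaction_id]
    except KeyError:
        raise IntegrationError(
            f"reaction {reaction_id!r} not found in the merged model"
        ) from None
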
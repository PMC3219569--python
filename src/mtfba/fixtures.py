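"""Deterministic toy tissue models with hand-derivable optima.

Three small, elementally and charge balanced tissue models — a
gluconeogenic liver, a glycolytic muscle, and a lipogenic fat tissue —
with proton-explicit lactate transport, plus scenario builders (Cori-like,
Alanine-like, absorptive-like) and synthetic expression call sets.  All
stoichiometric yields are integers so every optimum below has a closed
form; the manifest records those closed forms for use as test oracles.

Energy bookkeeping of the toys (per unit flux):

* glycolysis to lactate yields 2 ATP per glucose,
* lactate oxidation yields ``atp_per_lactate`` (default 15) ATP,
* pyruvate oxidation yields ``atp_per_pyruvate_pair``/2 (default 12.5) ATP,
* gluconeogenesis costs ``atp_per_glucose_synthesis`` (default 6) ATP.

With lactate input L and hepatic maintenance M, maximal hepatic glucose
output solves 2g + y = L, k*y >= c*g + M, i.e. g = (k*L - M)/(2k + c);
the defaults give 5/3 mmol/h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .context import ExpressionCallSet
from .integrate import (
    MassParams,
    MultiTissueModel,
    TissueModel,
    add_buffer,
    merge_models,
    tag_model,
)
from .model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
    make_met_id,
    parse_gpr,
    save_table,
)
from .simulate import ObjectiveStage, Scenario

#: formula and charge of every toy species
SPECIES: dict[str, tuple[str, int]] = {
    "glc": ("C6H12O6", 0),
    "lac": ("C3H5O3", -1),
    "pyr": ("C3H3O3", -1),
    "ala": ("C3H7NO2", 0),
    "urea": ("CH4N2O", 0),
    "nh4": ("H4N", 1),
    "o2": ("O2", 0),
    "co2": ("CO2", 0),
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "hco3": ("CHO3", -1),
    "atp": ("C10H12N5O13P3", -4),
    "adp": ("C10H12N5O10P2", -3),
    "pi": ("HO4P", -2),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "glgc": ("C6H10O5", 0),
    "glycerol": ("C3H8O3", 0),
    "oct": ("C8H15O2", -1),
    "tag": ("C27H50O6", 0),
}

#: glucose consumed per triacylglycerol in the fat toy (0.5 for the
#: glycerol backbone + 3 x 2 for the three octanoyl chains)
GLC_PER_TAG = 6.5

TISSUE_TAGS = {"liver": "h", "muscle": "m", "fat": "a"}

DEFAULT_MASS_PARAMS = {
    "liver": MassParams(1800.0, 0.8, 0.7, 0.0),
    "muscle": MassParams(28000.0, 1.0, 0.75, 0.0),
    "fat": MassParams(15000.0, 1.0, 0.2, 0.0),
}

BLOOD_WHITELIST = (
    "ala", "co2", "glc", "glycerol", "h2o", "lac", "nh4", "o2", "urea",
)


@dataclass
class ToyScenario:
    """Parameters of the toy system (all closed forms assume defaults
    unless noted)."""

    lactate_uptake: float = 6.0
    alanine_uptake: float = 6.0
    glucose_uptake: float = 10.0
    liver_atp_maintenance: float = 30.0
    muscle_atp_maintenance: float = 0.0
    absorptive_liver_maintenance: float = 16.0
    absorptive_muscle_maintenance: float = 2.0
    atp_per_lactate: int = 15
    atp_per_glucose_synthesis: int = 6
    atp_per_pyruvate_pair: int = 25
    fat_glucose_limit: float = 6.5
    proton_coupled: bool = True
    bound: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lactate_uptake", "alanine_uptake", "glucose_uptake",
            "liver_atp_maintenance", "muscle_atp_maintenance",
            "absorptive_liver_maintenance", "absorptive_muscle_maintenance",
            "fat_glucose_limit",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in (
            "atp_per_lactate", "atp_per_glucose_synthesis",
            "atp_per_pyruvate_pair",
        ):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ValueError(f"{name} must be a positive integer")
        if self.atp_per_glucose_synthesis < 4:
            # the proton coefficient of gluconeogenesis is (cost - 4)
            raise ValueError("atp_per_glucose_synthesis must be >= 4")


# ---------------------------------------------------------------------------
# building blocks


def _add_met(model: MetabolicModel, base: str, comp: str) -> str:
    mid = make_met_id(base, comp)
    if mid not in model.metabolites:
        formula, charge = SPECIES[base]
        model.add_metabolite(
            Metabolite(id=mid, base_id=base, compartment=comp,
                       formula=formula, charge=charge, name=base)
        )
    return mid


def _rxn(
    model: MetabolicModel,
    rid: str,
    stoich: dict[tuple[str, str], float],
    lb: float,
    ub: float,
    gpr: str = "",
    kind: ReactionKind = ReactionKind.INTERNAL,
    subsystem: str = "",
) -> Reaction:
    stoichiometry = {
        _add_met(model, base, comp): coef for (base, comp), coef in stoich.items()
    }
    return model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry=stoichiometry,
            lower_bound=lb,
            upper_bound=ub,
            gpr=parse_gpr(gpr),
            kind=kind,
            subsystem=subsystem,
        )
    )


def _exchange(model: MetabolicModel, base: str, bound: float) -> None:
    _rxn(
        model,
        f"EX_{base}",
        {(base, "e"): -1.0},
        -bound,
        bound,
        kind=ReactionKind.EXCHANGE,
        subsystem="exchange",
    )


def _lactate_transport(model: MetabolicModel, gpr: str, bound: float,
                       coupled: bool) -> None:
    """Monocarboxylate-style transporter.

    When coupled, the proton moves in symport with lactate; otherwise
    lactate crosses alone and a free proton diffusion reaction is added,
    decoupling the proton flow from the lactate flow.  Either way, blood
    proton balance requires the bicarbonate buffer whenever unprotonated
    lactate enters from the extra-system.
    """
    stoich: dict[tuple[str, str], float] = {("lac", "e"): -1.0, ("lac", "c"): 1.0}
    if coupled:
        stoich[("h", "e")] = -1.0
        stoich[("h", "c")] = 1.0
    _rxn(model, "T_lac", stoich, -bound, bound, gpr=gpr,
         kind=ReactionKind.TRANSPORTER, subsystem="transport")
    if not coupled:
        _diffusion(model, "h", bound)


def _diffusion(model: MetabolicModel, base: str, bound: float,
               gpr: str = "") -> None:
    _rxn(model, f"T_{base}", {(base, "e"): -1.0, (base, "c"): 1.0},
         -bound, bound, gpr=gpr, kind=ReactionKind.TRANSPORTER,
         subsystem="transport")


def _maintenance(model: MetabolicModel, bound: float) -> None:
    _rxn(model, "ATPM",
         {("atp", "c"): -1.0, ("h2o", "c"): -1.0,
          ("adp", "c"): 1.0, ("pi", "c"): 1.0, ("h", "c"): 1.0},
         0.0, bound, subsystem="energy")


def _biomass_stub(model: MetabolicModel, bound: float) -> None:
    _rxn(model, "BIOMASS",
         {("atp", "c"): -20.0, ("h2o", "c"): -20.0,
          ("adp", "c"): 20.0, ("pi", "c"): 20.0, ("h", "c"): 20.0},
         0.0, bound, kind=ReactionKind.BIOMASS, subsystem="biomass")


def _glycogen_storage(model: MetabolicModel, gpr: str, bound: float) -> None:
    _rxn(model, "GLYS",
         {("glc", "c"): -1.0, ("atp", "c"): -1.0,
          ("glgc", "c"): 1.0, ("adp", "c"): 1.0, ("pi", "c"): 1.0,
          ("h", "c"): 1.0},
         0.0, bound, gpr=gpr, subsystem="glycogen")
    _rxn(model, "GLYSTOR", {("glgc", "c"): -1.0}, 0.0, bound,
         kind=ReactionKind.BIOMASS, subsystem="glycogen")


def _glycolysis_to_lactate(model: MetabolicModel, gpr: str, bound: float) -> None:
    _rxn(model, "GLYC",
         {("glc", "c"): -1.0, ("adp", "c"): -2.0, ("pi", "c"): -2.0,
          ("lac", "c"): 2.0, ("atp", "c"): 2.0, ("h2o", "c"): 2.0},
         0.0, bound, gpr=gpr, subsystem="glycolysis")


def _glycolysis_to_pyruvate(model: MetabolicModel, gpr: str, bound: float) -> None:
    _rxn(model, "GLYCP",
         {("glc", "c"): -1.0, ("adp", "c"): -2.0, ("pi", "c"): -2.0,
          ("nad", "c"): -2.0, ("pyr", "c"): 2.0, ("atp", "c"): 2.0,
          ("h2o", "c"): 2.0, ("nadh", "c"): 2.0, ("h", "c"): 2.0},
         0.0, bound, gpr=gpr, subsystem="glycolysis")


def _respiration(model: MetabolicModel, gpr: str, bound: float) -> None:
    _rxn(model, "RESP",
         {("nadh", "c"): -2.0, ("o2", "c"): -1.0, ("h", "c"): -2.0,
          ("nad", "c"): 2.0, ("h2o", "c"): 2.0},
         0.0, bound, gpr=gpr, subsystem="energy")


# ---------------------------------------------------------------------------
# tissue builders


def _liver_model(params: ToyScenario) -> MetabolicModel:
    B = params.bound
    k = params.atp_per_lactate
    c = params.atp_per_glucose_synthesis
    j = params.atp_per_pyruvate_pair
    model = MetabolicModel("toy_liver", "toy gluconeogenic liver")

    _diffusion(model, "o2", B)
    _diffusion(model, "co2", B)
    _diffusion(model, "h2o", B)
    _rxn(model, "T_glc", {("glc", "e"): -1.0, ("glc", "c"): 1.0},
         -B, B, gpr="HGT1", kind=ReactionKind.TRANSPORTER, subsystem="transport")
    _lactate_transport(model, "HLT1", B, params.proton_coupled)
    _rxn(model, "T_ala", {("ala", "e"): -1.0, ("ala", "c"): 1.0},
         -B, B, gpr="HAT1", kind=ReactionKind.TRANSPORTER, subsystem="transport")
    _rxn(model, "T_urea", {("urea", "c"): -1.0, ("urea", "e"): 1.0},
         0.0, B, gpr="HUT1", kind=ReactionKind.TRANSPORTER, subsystem="transport")

    # lactate dehydrogenase (reversible redox link lac <-> pyr)
    _rxn(model, "LDH",
         {("lac", "c"): -1.0, ("nad", "c"): -1.0,
          ("pyr", "c"): 1.0, ("nadh", "c"): 1.0, ("h", "c"): 1.0},
         -B, B, gpr="HLDH1", subsystem="glycolysis")
    # gluconeogenesis from pyruvate, ATP cost c
    _rxn(model, "GNG",
         {("pyr", "c"): -2.0, ("atp", "c"): -float(c), ("nadh", "c"): -2.0,
          ("h2o", "c"): -float(c), ("glc", "c"): 1.0, ("adp", "c"): float(c),
          ("pi", "c"): float(c), ("nad", "c"): 2.0, ("h", "c"): float(c - 4)},
         0.0, B, gpr="HPCK1 and HFBP1", subsystem="gluconeogenesis")
    # complete lactate oxidation, ATP yield k
    _rxn(model, "LACOX",
         {("lac", "c"): -1.0, ("o2", "c"): -3.0, ("adp", "c"): -float(k),
          ("pi", "c"): -float(k), ("h", "c"): -float(k + 1),
          ("co2", "c"): 3.0, ("atp", "c"): float(k), ("h2o", "c"): float(k + 3)},
         0.0, B, gpr="HOXL1", subsystem="energy")
    # pyruvate oxidation, ATP yield j per 2 pyruvate
    _rxn(model, "PYROX",
         {("pyr", "c"): -2.0, ("o2", "c"): -5.0, ("adp", "c"): -float(j),
          ("pi", "c"): -float(j), ("h", "c"): -float(j + 2),
          ("co2", "c"): 6.0, ("atp", "c"): float(j), ("h2o", "c"): float(j + 4)},
         0.0, B, gpr="HPDH1", subsystem="energy")
    _respiration(model, "HETC1", B)
    # alanine deamination and urea synthesis
    _rxn(model, "ALADA",
         {("ala", "c"): -1.0, ("h2o", "c"): -1.0, ("nad", "c"): -1.0,
          ("pyr", "c"): 1.0, ("nh4", "c"): 1.0, ("nadh", "c"): 1.0,
          ("h", "c"): 1.0},
         0.0, B, gpr="HALT1", subsystem="amino acid metabolism")
    _rxn(model, "UREAS",
         {("nh4", "c"): -2.0, ("co2", "c"): -1.0,
          ("urea", "c"): 1.0, ("h2o", "c"): 1.0, ("h", "c"): 2.0},
         0.0, B, gpr="HCPS1", subsystem="urea cycle")
    _glycolysis_to_pyruvate(model, "HGLK1", B)
    _glycogen_storage(model, "HGYS1", B)
    _maintenance(model, B)
    _biomass_stub(model, B)
    for base in ("glc", "lac", "ala", "o2", "co2", "urea", "h", "h2o"):
        _exchange(model, base, B)
    model.set_objective({"GNG": 1.0})
    model.validate()
    return model


def _muscle_model(params: ToyScenario) -> MetabolicModel:
    B = params.bound
    model = MetabolicModel("toy_muscle", "toy glycolytic muscle")
    _diffusion(model, "h2o", B)
    # ammonium/proton antiport: keeps the cytosol proton-balanced when
    # nitrogen enters for alanine synthesis (NH3 diffusion + H+ return)
    _rxn(model, "T_nh4",
         {("nh4", "e"): -1.0, ("h", "c"): -1.0,
          ("nh4", "c"): 1.0, ("h", "e"): 1.0},
         -B, B, gpr="MNT1", kind=ReactionKind.TRANSPORTER,
         subsystem="transport")
    _rxn(model, "T_glc", {("glc", "e"): -1.0, ("glc", "c"): 1.0},
         -B, B, gpr="MGT4", kind=ReactionKind.TRANSPORTER, subsystem="transport")
    _lactate_transport(model, "MLT1", B, params.proton_coupled)
    _rxn(model, "T_ala", {("ala", "c"): -1.0, ("ala", "e"): 1.0},
         0.0, B, gpr="MAT1", kind=ReactionKind.TRANSPORTER, subsystem="transport")
    _glycolysis_to_lactate(model, "MGLY1", B)
    _glycolysis_to_pyruvate(model, "MGLY2", B)
    # alanine synthesis (reverse deamination) for nitrogen export
    _rxn(model, "ALAS",
         {("pyr", "c"): -1.0, ("nh4", "c"): -1.0, ("nadh", "c"): -1.0,
          ("h", "c"): -1.0, ("ala", "c"): 1.0, ("h2o", "c"): 1.0,
          ("nad", "c"): 1.0},
         0.0, B, gpr="MALT1", subsystem="amino acid metabolism")
    _glycogen_storage(model, "MGYS1", B)
    _maintenance(model, B)
    _biomass_stub(model, B)
    for base in ("glc", "lac", "ala", "nh4", "h", "h2o"):
        _exchange(model, base, B)
    model.set_objective({"ATPM": 1.0})
    model.validate()
    return model


def _fat_model(params: ToyScenario) -> MetabolicModel:
    B = params.bound
    model = MetabolicModel("toy_fat", "toy lipogenic fat")
    _diffusion(model, "o2", B)
    _diffusion(model, "co2", B)
    _diffusion(model, "h2o", B)
    _diffusion(model, "glycerol", B, gpr="AAQP1")
    _rxn(model, "T_glc", {("glc", "e"): -1.0, ("glc", "c"): 1.0},
         -B, B, gpr="AGT4", kind=ReactionKind.TRANSPORTER, subsystem="transport")
    _lactate_transport(model, "ALT1", B, params.proton_coupled)
    _glycolysis_to_lactate(model, "GLYC", B)
    model.reactions["GLYC"].gpr = parse_gpr("AGLY1")
    # glycerol backbone synthesis (reductive)
    _rxn(model, "GLYCSYN",
         {("glc", "c"): -1.0, ("nadh", "c"): -2.0, ("h", "c"): -2.0,
          ("glycerol", "c"): 2.0, ("nad", "c"): 2.0},
         0.0, B, gpr="AGPD1", subsystem="lipid synthesis")
    # fatty acid (octanoate) synthesis from glucose
    _rxn(model, "OCTSYN",
         {("glc", "c"): -2.0, ("nad", "c"): -2.0,
          ("oct", "c"): 1.0, ("co2", "c"): 4.0, ("nadh", "c"): 2.0,
          ("h2o", "c"): 2.0, ("h", "c"): 3.0},
         0.0, B, gpr="AFAS1", subsystem="lipid synthesis")
    # esterification to triacylglycerol
    _rxn(model, "ESTER",
         {("glycerol", "c"): -1.0, ("oct", "c"): -3.0, ("h", "c"): -3.0,
          ("tag", "c"): 1.0, ("h2o", "c"): 3.0},
         0.0, B, gpr="ADGA1", subsystem="lipid synthesis")
    _respiration(model, "AETC1", B)
    # triacylglycerol storage drain (the adipocyte's storage objective)
    _rxn(model, "TAGSTOR", {("tag", "c"): -1.0}, 0.0, B,
         kind=ReactionKind.BIOMASS, subsystem="lipid storage")
    _maintenance(model, B)
    _biomass_stub(model, B)
    for base in ("glc", "lac", "o2", "co2", "glycerol", "h", "h2o"):
        _exchange(model, base, B)
    model.set_objective({"TAGSTOR": 1.0})
    model.validate()
    return model


_BUILDERS = {"liver": _liver_model, "muscle": _muscle_model, "fat": _fat_model}


def toy_tissue(kind: str, params: ToyScenario | None = None) -> TissueModel:
    """Build one toy tissue, tagged with its canonical tissue tag."""
    params = params or ToyScenario()
    if kind not in _BUILDERS:
        raise ValueError(f"unknown toy tissue kind {kind!r}; "
                         f"expected one of {sorted(_BUILDERS)}")
    model = _BUILDERS[kind](params)
    return tag_model(
        model,
        TISSUE_TAGS[kind],
        biomass_reaction_id="BIOMASS",
        mass_params=DEFAULT_MASS_PARAMS[kind],
    )


def toy_multitissue(
    params: ToyScenario | None = None,
    buffer: bool = True,
    kinds: tuple[str, ...] = ("liver", "muscle", "fat"),
) -> MultiTissueModel:
    """Merge the toy tissues through blood, optionally adding the buffer."""
    params = params or ToyScenario()
    tissues = [toy_tissue(kind, params) for kind in kinds]
    available = {
        met.base_id
        for tissue in tissues
        for met in tissue.model.metabolites.values()
        if met.compartment == tissue.extracellular_compartment
    }
    whitelist = [b for b in BLOOD_WHITELIST if b in available]
    mt = merge_models(tissues, whitelist, exchange_bound=params.bound)
    if buffer:
        mt = add_buffer(mt, exchange_bound=params.bound)
    return mt


# ---------------------------------------------------------------------------
# scenarios


def _open(lo: float, hi: float) -> tuple[float, float]:
    return (lo, hi)


def cori_scenario(params: ToyScenario | None = None) -> Scenario:
    """Lactate in, hepatic glucose out; fat deactivated."""
    p = params or ToyScenario()
    B = p.bound
    return Scenario(
        name="cori",
        close_exchanges=True,
        deactivate_tissues=["a"],
        bounds={
            "EX_lac[bl]": (-p.lactate_uptake, -p.lactate_uptake),
            "EX_glc[bl]": (0.0, B),
            "EX_o2[bl]": (-B, 0.0),
            "EX_co2[bl]": (-B, B),
            "EX_hco3[bl]": (-B, B),
            "EX_h2o[bl]": (-B, B),
            "ATPM[h]": (p.liver_atp_maintenance, B),
            "ATPM[m]": (p.muscle_atp_maintenance, B),
        },
        objectives=[ObjectiveStage({"EX_glc[bl]": 1.0}, "max", 1.0)],
        carbon_sources=["EX_lac[bl]"],
        sinks={"glucose": ["EX_glc[bl]"]},
    )


def alanine_scenario(params: ToyScenario | None = None) -> Scenario:
    """Alanine in, hepatic glucose and urea out; fat deactivated."""
    p = params or ToyScenario()
    B = p.bound
    return Scenario(
        name="alanine",
        close_exchanges=True,
        deactivate_tissues=["a"],
        bounds={
            "EX_ala[bl]": (-p.alanine_uptake, -p.alanine_uptake),
            "EX_glc[bl]": (0.0, B),
            "EX_urea[bl]": (0.0, B),
            "EX_o2[bl]": (-B, 0.0),
            "EX_co2[bl]": (-B, B),
            "EX_hco3[bl]": (-B, B),
            "EX_h2o[bl]": (-B, B),
            "ATPM[h]": (p.liver_atp_maintenance, B),
            "ATPM[m]": (p.muscle_atp_maintenance, B),
        },
        objectives=[ObjectiveStage({"EX_glc[bl]": 1.0}, "max", 1.0)],
        carbon_sources=["EX_ala[bl]"],
        sinks={"glucose": ["EX_glc[bl]"], "urea": ["EX_urea[bl]"]},
    )


def absorptive_scenario(params: ToyScenario | None = None) -> Scenario:
    """Glucose in; storage objectives optimized lexicographically:
    fat triacylglycerol first, then liver+muscle glycogen."""
    p = params or ToyScenario()
    B = p.bound
    return Scenario(
        name="absorptive",
        close_exchanges=True,
        bounds={
            "EX_glc[bl]": (-p.glucose_uptake, 0.0),
            "EX_o2[bl]": (-B, 0.0),
            "EX_co2[bl]": (-B, B),
            "EX_hco3[bl]": (-B, B),
            "EX_h2o[bl]": (-B, B),
            "EX_urea[bl]": (0.0, B),
            "EX_glycerol[bl]": (0.0, B),
            "T_glc[a]": (0.0, p.fat_glucose_limit),
            "ATPM[h]": (p.absorptive_liver_maintenance, B),
            "ATPM[m]": (p.absorptive_muscle_maintenance, B),
        },
        objectives=[
            ObjectiveStage({"TAGSTOR[a]": 1.0}, "max", 1.0),
            ObjectiveStage({"GLYSTOR[h]": 1.0, "GLYSTOR[m]": 1.0}, "max", 1.0),
        ],
        carbon_sources=["EX_glc[bl]"],
        sinks={
            "triacylglycerol": ["TAGSTOR[a]"],
            "glycogen": ["GLYSTOR[h]", "GLYSTOR[m]"],
        },
    )


def starvation_scenario(params: ToyScenario | None = None) -> Scenario:
    """Prolonged-starvation baseline for context extraction: peripheral
    gluconeogenic substrate (alanine, standing in for muscle protein
    breakdown) becomes the input and hepatic glucose output the
    objective."""
    scenario = alanine_scenario(params)
    scenario.name = "starvation"
    return scenario


SCENARIO_BUILDERS = {
    "cori": cori_scenario,
    "alanine": alanine_scenario,
    "absorptive": absorptive_scenario,
    "starvation": starvation_scenario,
}


# ---------------------------------------------------------------------------
# closed-form optima


def manifest(params: ToyScenario | None = None) -> dict:
    """Closed-form optima of the toy scenarios (valid at the default
    parameter regime; see the notes key)."""
    p = params or ToyScenario()
    k = p.atp_per_lactate
    c = p.atp_per_glucose_synthesis
    L = p.lactate_uptake
    A = p.alanine_uptake
    M = p.liver_atp_maintenance
    cori_glc = (k * L - M) / (2 * k + c)
    ala_glc = (k * A - M) / (2 * k + c)
    tag = p.fat_glucose_limit / GLC_PER_TAG
    # absorptive glycogen: the g0 glucose left after fat and muscle take
    # theirs goes to glycogen directly; muscle's exported lactate (2 ATP of
    # maintenance per glucose -> lac mmol lactate) is split between
    # oxidation (y*, just enough ATP for hepatic maintenance, glycogen
    # synthesis, and gluconeogenesis) and gluconeogenesis back to glucose.
    g0 = (
        p.glucose_uptake
        - p.fat_glucose_limit
        - p.absorptive_muscle_maintenance / 2.0
    )
    lac = p.absorptive_muscle_maintenance
    y_star = (p.absorptive_liver_maintenance + g0 + (c + 1) / 2.0 * lac) / (
        k + (c + 1) / 2.0
    )
    glycogen = g0 + max(0.0, lac - y_star) / 2.0
    return {
        "params": {kk: vv for kk, vv in vars(p).items()},
        "cori": {
            "glucose_optimum": cori_glc,
            "carbon_split": {
                "glucose": 6 * cori_glc / (3 * L),
                "maintenance": 1.0 - 6 * cori_glc / (3 * L),
            },
        },
        "alanine": {
            "glucose_optimum": ala_glc,
            "carbon_split": {
                "glucose": 6 * ala_glc / (3 * A),
                "urea": (A / 2.0) / (3 * A),
                "maintenance": 1.0 - 6 * ala_glc / (3 * A) - 1.0 / 6.0,
            },
        },
        "absorptive": {
            "triacylglycerol_optimum": tag,
            "glycogen_optimum": glycogen,
        },
        "notes": (
            "closed forms assume muscle_atp_maintenance feeds only the Cori/"
            "Alanine scenarios at zero and that hepatic lactate ATP covers "
            "absorptive maintenance; outside the default regime solve the LP"
        ),
    }


# ---------------------------------------------------------------------------
# expression call sets

EXPRESSION_SCENARIOS = ("identical", "drop_redundant", "drop_essential")

#: gene whose loss leaves a redundant energy route (pyruvate oxidation;
#: the LDH + lactate-oxidation route still meets the RMF)
REDUNDANT_GENE = "HPDH1"
#: gene whose loss blocks the only gluconeogenesis route (GNG is an AND
#: complex, so losing one subunit silences the reaction)
ESSENTIAL_GENE = "HFBP1"

_GROUPS = ("g1", "g2")


def toy_expression(
    mt: MultiTissueModel,
    scenario: str = "identical",
    seed: int = 0,
    n_samples: int = 4,
) -> ExpressionCallSet:
    """Synthetic two-group expression call sets over the toy genes.

    ``identical``: unanimous P everywhere.  ``drop_redundant``: group g2
    loses the redundant pyruvate-oxidation gene.  ``drop_essential``:
    group g2 loses one subunit of the gluconeogenesis complex.  A decoy
    gene (absent in one random sample of g1, position seeded) is added
    per tissue as material for stability analysis; it maps to no
    reaction.
    """
    if scenario not in EXPRESSION_SCENARIOS:
        raise ValueError(
            f"unknown expression scenario {scenario!r}; "
            f"expected one of {EXPRESSION_SCENARIOS}"
        )
    rng = np.random.default_rng(seed)
    genes_by_tissue: dict[str, set[str]] = {}
    for rid, rxn in mt.model.reactions.items():
        tissue, _ = mt.provenance[rid]
        if tissue == "bl":
            continue
        genes_by_tissue.setdefault(tissue, set()).update(rxn.gpr.genes())
    calls = ExpressionCallSet()
    dropped = {
        "drop_redundant": REDUNDANT_GENE,
        "drop_essential": ESSENTIAL_GENE,
    }.get(scenario)
    for tissue in sorted(genes_by_tissue):
        genes = sorted(genes_by_tissue[tissue]) + [f"XDECOY_{tissue}"]
        decoy_sample = int(rng.integers(n_samples))
        for group in _GROUPS:
            for i in range(n_samples):
                sample = f"{tissue}_{group}_s{i}"
                for gene in genes:
                    call = "P"
                    if gene == dropped and group == "g2":
                        call = "A"
                    if gene.startswith("XDECOY_") and group == "g1" and i == decoy_sample:
                        call = "A"
                    calls.add_call(tissue, group, sample, gene, call)
    calls.validate()
    return calls


# ---------------------------------------------------------------------------
# on-disk emission


def write_toys(
    out_dir: str | Path,
    params: ToyScenario | None = None,
    buffer: bool = True,
) -> dict:
    """Emit toy tissue models, the merged model (table format), the four
    scenario files, and a manifest JSON with the closed-form optima.
    Same parameters (incl. seed) give byte-identical files."""
    params = params or ToyScenario()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for kind in ("liver", "muscle", "fat"):
        save_table(toy_tissue(kind, params).model, out / f"{kind}.tsv")
    mt = toy_multitissue(params, buffer=buffer)
    save_table(mt.model, out / "multi_tissue.tsv")
    for name, builder in SCENARIO_BUILDERS.items():
        builder(params).to_yaml(out / f"{name}.yaml")
    data = manifest(params)
    (out / "manifest.json").write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    return data
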
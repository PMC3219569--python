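"""Analyses against the published tissue models (when available).

The published adipocyte/hepatocyte/myocyte SBML models are distributed as
journal supplementary material and are not bundled here.  Drop the three
SBML files into a directory (default ``data/supplementary``) and these
helpers will locate them by filename, merge hepatocyte + myocyte through
the blood compartment, and recompute the published comparison numbers:
reaction-sharing counts, the Cori/Alanine carbon splits, and the
flux-span table metrics.

Scenario constraints (uptake rates, maintenance bounds) are reconstructed
from the published description, not shipped with the models; treat the
cycle results as a faithful re-implementation of the stated procedure
rather than a bit-exact rerun.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .integrate import (
    MultiTissueModel,
    add_buffer,
    merge_models,
    tag_model,
)
from .model_core import MetabolicModel, ReactionKind, load_model
from .simulate import (
    ObjectiveStage,
    carbon_input,
    carbon_split,
    classify,
    detect_loops,
    fba,
    fva,
)

#: filename fragments used to locate each model (case-insensitive)
MODEL_PATTERNS = {
    "a": ("adipo", "am_", "_am", "fat"),
    "h": ("hepato", "hm_", "_hm", "liver"),
    "m": ("myo", "mm_", "_mm", "muscle"),
}

#: base ids of the blood metabolites in BiGG-style nomenclature
BIGG_SPECIES = {
    "glucose": "glc_D",
    "lactate": "lac_L",
    "alanine": "ala_L",
    "urea": "urea",
    "oxygen": "o2",
    "co2": "co2",
    "water": "h2o",
    "proton": "h",
    "bicarbonate": "hco3",
    "ammonium": "nh4",
}


class SupplementaryModelsMissing(FileNotFoundError):
    """The published SBML models were not found on disk."""


def find_model_files(directory: str | Path) -> dict[str, Path]:
    """Locate the three cell-specific SBML files by filename fragment."""
    directory = Path(directory)
    if not directory.is_dir():
        raise SupplementaryModelsMissing(
            f"supplementary model directory {directory} does not exist"
        )
    found: dict[str, Path] = {}
    for path in sorted(directory.glob("*.xml")) + sorted(directory.glob("*.sbml")):
        lower = path.name.lower()
        if "multi" in lower:
            continue
        for tag, fragments in MODEL_PATTERNS.items():
            if tag not in found and any(f in lower for f in fragments):
                found[tag] = path
    missing = set(MODEL_PATTERNS) - set(found)
    if missing:
        raise SupplementaryModelsMissing(
            f"could not locate models for tags {sorted(missing)} in {directory}"
        )
    return found


def load_tissue_models(directory: str | Path) -> dict[str, MetabolicModel]:
    return {tag: load_model(path) for tag, path in find_model_files(directory).items()}


def intracellular_reaction_ids(model: MetabolicModel) -> set[str]:
    """Reaction ids excluding system-boundary exchanges."""
    return {
        rid
        for rid, rxn in model.reactions.items()
        if rxn.kind is not ReactionKind.EXCHANGE
    }


def reaction_sharing(models: dict[str, MetabolicModel]) -> dict[str, int]:
    """Pairwise/three-way shared intracellular reaction counts on original
    reaction identifiers (the published Venn breakdown)."""
    sets = {tag: intracellular_reaction_ids(model) for tag, model in models.items()}
    core = sets["a"] & sets["h"] & sets["m"]
    return {
        "core": len(core),
        "hm_am": len((sets["h"] & sets["a"]) - sets["m"]),
        "hm_mm": len((sets["h"] & sets["m"]) - sets["a"]),
        "am_mm": len((sets["a"] & sets["m"]) - sets["h"]),
        "only_a": len(sets["a"] - sets["h"] - sets["m"]),
        "only_h": len(sets["h"] - sets["a"] - sets["m"]),
        "only_m": len(sets["m"] - sets["a"] - sets["h"]),
    }


def _exchange_id(mt: MultiTissueModel, base_id: str) -> str:
    ex = f"EX_{base_id}[bl]"
    if ex not in mt.model.reactions:
        raise KeyError(f"blood exchange for {base_id!r} not present after merging")
    return ex


def build_hm_mm_model(models: dict[str, MetabolicModel]) -> MultiTissueModel:
    """Merge hepatocyte and myocyte through the blood compartment with the
    bicarbonate buffer, whitelisting the cycle metabolites."""
    tissues = [tag_model(models["h"], "h"), tag_model(models["m"], "m")]
    whitelist = [
        BIGG_SPECIES[name]
        for name in (
            "glucose", "lactate", "alanine", "urea", "oxygen", "co2",
            "water", "ammonium",
        )
    ]
    available = {
        met.base_id
        for tissue in tissues
        for met in tissue.model.metabolites.values()
        if met.compartment == tissue.extracellular_compartment
    }
    mt = merge_models(tissues, [b for b in whitelist if b in available])
    return add_buffer(mt)


@dataclass
class CycleResult:
    glucose_fraction: float
    urea_fraction: float | None
    maintenance_fraction: float
    carbon_input_mmolC: float
    hm_classification: dict
    mm_classification: dict


def _tissue_partition(mt: MultiTissueModel, tag: str) -> list[str]:
    return [rid for rid, (t, _) in mt.provenance.items() if t == tag]


def cycle_simulation(
    mt: MultiTissueModel,
    cycle: str,
    uptake: float = 1.0,
    tol: float = 1e-6,
) -> CycleResult:
    """Recompute a gluconeogenic cycle on the merged published models.

    ``cycle`` is ``"cori"`` (lactate in) or ``"alanine"`` (alanine in).
    The sole extra-system carbon input is fixed at ``uptake`` mmol/h,
    hepatic glucose output is maximized, and the carbon split plus the
    per-tissue flux-span classification are reported.
    """
    if cycle not in ("cori", "alanine"):
        raise ValueError(f"unknown cycle {cycle!r}")
    substrate = BIGG_SPECIES["lactate" if cycle == "cori" else "alanine"]
    model = mt.model.copy()
    open_both = {
        BIGG_SPECIES[n] for n in ("co2", "water", "bicarbonate")
    }
    uptake_only = {BIGG_SPECIES["oxygen"]}
    secrete_only = {BIGG_SPECIES["glucose"], BIGG_SPECIES["urea"]}
    for rxn in model.exchanges:
        base = next(iter(rxn.stoichiometry))
        base_id = model.metabolites[base].base_id
        if base_id == substrate:
            rxn.bounds = (-uptake, -uptake)
        elif base_id in open_both:
            rxn.bounds = (-1000.0, 1000.0)
        elif base_id in uptake_only:
            rxn.bounds = (-1000.0, 0.0)
        elif base_id in secrete_only:
            rxn.bounds = (0.0, 1000.0)
        else:
            rxn.bounds = (0.0, 0.0)  # no other extra-system carbon
    glc_ex = f"EX_{BIGG_SPECIES['glucose']}[bl]"
    urea_ex = f"EX_{BIGG_SPECIES['urea']}[bl]"
    sub_ex = f"EX_{substrate}[bl]"
    objective = {glc_ex: 1.0}
    solution = fba(model, objective, "max")
    if not solution.optimal:
        raise RuntimeError(f"{cycle} cycle simulation is {solution.status}")
    sinks = {"glucose": [glc_ex]}
    if cycle == "alanine" and urea_ex in model.reactions:
        sinks["urea"] = [urea_ex]
    split = carbon_split(model, solution, [sub_ex], sinks)
    total_c = carbon_input(model, solution, [sub_ex])

    loops = detect_loops(model, tol)
    result = fva(model, fixes=[ObjectiveStage(objective, "max", 1.0)])
    classifications = {}
    for tag in ("h", "m"):
        partition = _tissue_partition(mt, tag)
        sub = type(result)(
            minimum={r: result.minimum[r] for r in partition},
            maximum={r: result.maximum[r] for r in partition},
        )
        cls = classify(sub, loops & set(partition), total_c, tol)
        classifications[tag] = {
            "mean_nonzero_span": cls.mean_nonzero_span,
            "loops": len(cls.loops),
            "zero": len(cls.zero),
            "fixed": len(cls.fixed_nonzero),
            "variable": len(cls.variable),
        }
    return CycleResult(
        glucose_fraction=split["glucose"],
        urea_fraction=split.get("urea"),
        maintenance_fraction=split["maintenance"],
        carbon_input_mmolC=total_c,
        hm_classification=classifications["h"],
        mm_classification=classifications["m"],
    )


def individual_tissue_span(
    mt: MultiTissueModel,
    tag: str,
    cycle: str,
    uptake: float = 1.0,
    tol: float = 1e-6,
) -> dict:
    """Individual-tissue variant: other tissues inactivated, extra-system
    exchanges opened, FVA spans of the surviving tissue classified."""
    others = [t for t in mt.tissue_tags if t != tag]
    individual = mt.deactivated(others)
    model = individual.model.copy()
    substrate = BIGG_SPECIES["lactate" if cycle == "cori" else "alanine"]
    sub_ex = None
    for rxn in model.exchanges:
        base = next(iter(rxn.stoichiometry))
        base_id = model.metabolites[base].base_id
        if base_id == substrate:
            rxn.bounds = (-uptake, -uptake)
            sub_ex = rxn.id
        else:
            rxn.bounds = (-1000.0, 1000.0)
    if sub_ex is None:
        raise KeyError(f"no exchange for substrate {substrate!r}")
    glc_ex = f"EX_{BIGG_SPECIES['glucose']}[bl]"
    objective = {glc_ex: 1.0}
    solution = fba(model, objective, "max")
    if not solution.optimal:
        raise RuntimeError(f"individual {tag} ({cycle}) is {solution.status}")
    total_c = carbon_input(model, solution, [sub_ex])
    loops = detect_loops(model, tol)
    partition = _tissue_partition(mt, tag)
    result = fva(model, reactions=partition,
                 fixes=[ObjectiveStage(objective, "max", 1.0)])
    cls = classify(result, loops & set(partition), total_c, tol)
    return {
        "mean_nonzero_span": cls.mean_nonzero_span,
        "loops": len(cls.loops),
        "zero": len(cls.zero),
        "fixed": len(cls.fixed_nonzero),
        "variable": len(cls.variable),
    }
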
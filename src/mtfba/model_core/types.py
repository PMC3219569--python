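"""Domain types for constraint-based metabolic models.

Identifier convention: metabolite ids are ``base[compartment]`` where the
compartment label combines an optional tissue tag with the subcellular
location, e.g. ``glc[h_c]`` for cytosolic glucose in the hepatocyte
compartment and ``glc[bl]`` for blood glucose.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Mapping

import numpy as np

from .gpr import GPRRule

DEFAULT_BOUND = 1000.0

_MET_ID = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")
_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*(?:\.\d+)?)")


class ModelConsistencyError(ValueError):
    """A model references entities that do not exist or violates an invariant."""


class FormulaError(ValueError):
    """A chemical formula string could not be parsed."""


def split_met_id(met_id: str) -> tuple[str, str]:
    """Split ``base[comp]`` into ``(base, comp)``."""
    m = _MET_ID.match(met_id)
    if not m:
        raise ValueError(f"metabolite id {met_id!r} is not of the form base[compartment]")
    return m.group("base"), m.group("comp")


def make_met_id(base_id: str, compartment: str) -> str:
    return f"{base_id}[{compartment}]"


def parse_formula(formula: str) -> Dict[str, float]:
    """Parse a Hill-notation formula into an element -> count map.

    Counts may be fractional (average formulas of lumped species).
    """
    if formula is None:
        raise FormulaError("formula is None")
    stripped = formula.strip()
    if not stripped:
        raise FormulaError("formula is empty")
    pos = 0
    out: Dict[str, float] = {}
    for m in _FORMULA_TOKEN.finditer(stripped):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element = m.group(1)
        count = float(m.group(2)) if m.group(2) else 1.0
        if count < 0:
            raise FormulaError(f"negative element count in {formula!r}")
        out[element] = out.get(element, 0.0) + count
    if pos != len(stripped):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return out


class ReactionKind(str, Enum):
    INTERNAL = "internal"
    TRANSPORTER = "transporter"
    EXCHANGE = "exchange"
    BIOMASS = "biomass"
    BUFFER = "buffer"


@dataclass
class Metabolite:
    """A chemical species in one compartment."""

    id: str
    base_id: str = ""
    compartment: str = ""
    name: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.base_id or not self.compartment:
            base, comp = split_met_id(self.id)
            self.base_id = self.base_id or base
            self.compartment = self.compartment or comp
        if self.id != make_met_id(self.base_id, self.compartment):
            raise ValueError(
                f"metabolite id {self.id!r} disagrees with "
                f"base_id/compartment {self.base_id!r}/{self.compartment!r}"
            )
        if self.formula is not None:
            parse_formula(self.formula)  # raises FormulaError if malformed

    def elements(self) -> Dict[str, float] | None:
        """Element -> count map, or None when no formula is set."""
        if self.formula is None:
            return None
        return parse_formula(self.formula)

    def carbon_count(self) -> float | None:
        elems = self.elements()
        if elems is None:
            return None
        return elems.get("C", 0.0)

    def copy(self) -> "Metabolite":
        return _copy.copy(self)


@dataclass
class Reaction:
    """A stoichiometric transformation with flux bounds and a GPR rule.

    Negative stoichiometric coefficients denote substrates.  Bounds are in
    mmol/h (per gDW before rescaling, per body after).  Reversibility is
    encoded as ``lower_bound < 0``.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRRule = field(default_factory=GPRRule)
    subsystem: str = ""
    kind: ReactionKind = ReactionKind.INTERNAL
    name: str = ""

    def __post_init__(self) -> None:
        self.kind = ReactionKind(self.kind)
        if not isinstance(self.gpr, GPRRule):
            raise TypeError(f"reaction {self.id}: gpr must be a GPRRule")
        self.validate()

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ModelConsistencyError(f"reaction {self.id}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelConsistencyError(
                    f"reaction {self.id}: zero coefficient for {met}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelConsistencyError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.kind is ReactionKind.EXCHANGE and len(self.stoichiometry) != 1:
            raise ModelConsistencyError(
                f"reaction {self.id}: exchange reactions carry exactly one "
                f"metabolite, got {len(self.stoichiometry)}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value: tuple[float, float]) -> None:
        self.lower_bound, self.upper_bound = float(value[0]), float(value[1])
        if self.lower_bound > self.upper_bound:
            raise ModelConsistencyError(
                f"reaction {self.id}: lower_bound > upper_bound"
            )

    def substrates(self) -> Dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> Dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    def equation_string(self) -> str:
        """Human/machine readable equation, e.g. ``2 a[c] + b[c] -> c[c]``."""

        def side(items: Dict[str, float]) -> str:
            parts = []
            for met in sorted(items):
                coef = items[met]
                if coef == 1:
                    parts.append(met)
                else:
                    parts.append(f"{format_number(coef)} {met}")
            return " + ".join(parts)

        return f"{side(self.substrates())} -> {side(self.products())}".strip()

    def copy(self) -> "Reaction":
        new = _copy.copy(self)
        new.stoichiometry = dict(self.stoichiometry)
        return new


def format_number(x: float) -> str:
    """Deterministic, round-trip-stable decimal rendering of a float."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


class MetabolicModel:
    """A constraint-based metabolic model.

    Holds registries of metabolites, reactions, genes, and compartments,
    plus a linear objective (reaction id -> coefficient).  The
    stoichiometric matrix S (m metabolites x n reactions) is derived on
    demand.
    """

    def __init__(self, model_id: str = "model", name: str = ""):
        self.id = model_id
        self.name = name or model_id
        self.metabolites: Dict[str, Metabolite] = {}
        self.reactions: Dict[str, Reaction] = {}
        self.objective: Dict[str, float] = {}
        self.genes: set[str] = set()
        self.compartments: set[str] = set()

    # -- construction -------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelConsistencyError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met
        self.compartments.add(met.compartment)
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelConsistencyError(f"duplicate reaction id {rxn.id!r}")
        missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
        if missing:
            raise ModelConsistencyError(
                f"reaction {rxn.id}: dangling metabolite reference(s) {missing}"
            )
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.gpr.genes()
        return rxn

    def remove_reaction(self, rxn_id: str) -> Reaction:
        try:
            rxn = self.reactions.pop(rxn_id)
        except KeyError:
            raise ModelConsistencyError(f"unknown reaction {rxn_id!r}") from None
        self.objective.pop(rxn_id, None)
        return rxn

    def set_objective(self, coefficients: Mapping[str, float]) -> None:
        missing = [r for r in coefficients if r not in self.reactions]
        if missing:
            raise ModelConsistencyError(
                f"objective references unknown reaction(s) {missing}"
            )
        self.objective = dict(coefficients)

    # -- queries ------------------------------------------------------

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind is ReactionKind.EXCHANGE]

    def reactions_of_kind(self, kind: ReactionKind) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind is kind]

    def metabolite_reactions(self) -> Dict[str, list[str]]:
        """Metabolite id -> list of reaction ids touching it."""
        out: Dict[str, list[str]] = {m: [] for m in self.metabolites}
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                out[met].append(rxn.id)
        return out

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S with one row per metabolite and one column per reaction."""
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[met], j] = coef
        return S, met_ids, rxn_ids

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate()
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ModelConsistencyError(
                        f"reaction {rxn.id}: dangling metabolite {met!r}"
                    )
        for rid in self.objective:
            if rid not in self.reactions:
                raise ModelConsistencyError(
                    f"objective references unknown reaction {rid!r}"
                )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelConsistencyError(
                    f"metabolite {met.id}: unregistered compartment"
                )

    def prune_unused_metabolites(self) -> list[str]:
        """Drop metabolites no reaction touches; returns removed ids."""
        used: set[str] = set()
        for rxn in self.reactions.values():
            used |= set(rxn.stoichiometry)
        removed = [m for m in self.metabolites if m not in used]
        for mid in removed:
            del self.metabolites[mid]
        self.compartments = {m.compartment for m in self.metabolites.values()}
        return removed

    def copy(self, model_id: str | None = None) -> "MetabolicModel":
        new = MetabolicModel(model_id or self.id, self.name)
        for met in self.metabolites.values():
            new.add_metabolite(met.copy())
        for rxn in self.reactions.values():
            new.add_reaction(rxn.copy())
        new.objective = dict(self.objective)
        new.genes = set(self.genes)
        new.compartments = set(self.compartments)
        return new

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


def net_formula_and_charge(
    model: MetabolicModel, rxn: Reaction
) -> tuple[Dict[str, float], float] | None:
    """Net element and charge production of a reaction (None if uncheckable).

    A balanced reaction has all-zero nets.  Returns None when any
    participating metabolite lacks a formula or charge.
    """
    net: Dict[str, float] = {}
    net_charge = 0.0
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolites[met_id]
        if met.formula is None or met.charge is None:
            return None
        for element, count in parse_formula(met.formula).items():
            net[element] = net.get(element, 0.0) + coef * count
        net_charge += coef * met.charge
    net = {e: c for e, c in net.items() if abs(c) > 1e-9}
    return net, net_charge


def iter_reactions(model: MetabolicModel, ids: Iterable[str] | None = None):
    if ids is None:
        yield from model.reactions.values()
    else:
        for rid in ids:
            if rid not in model.reactions:
                raise ModelConsistencyError(f"unknown reaction {rid!r}")
            yield model.reactions[rid]
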
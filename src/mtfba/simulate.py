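"""LP-based analysis of metabolic models.

Flux balance analysis (maximize c'v subject to S v = 0, lb <= v <= ub),
flux variability analysis, flux-span classification, internal-loop
detection via closed-exchange FVA, lexicographic (Pareto-style)
multi-objective optimization, and carbon-fate accounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import optlang
import pandas as pd
import yaml

from .model_core import MetabolicModel, ReactionKind
from .integrate import MultiTissueModel

ZERO_TOL = 1e-6
FEASIBILITY_TOL = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """Solver failed for a reason other than infeasibility/unboundedness."""


class InfeasibleScenarioError(RuntimeError):
    """A fix or scenario constraint made the model infeasible."""


# ---------------------------------------------------------------------------
# LP construction


def _finite(bound: float) -> float | None:
    """Infinite bounds become free (None); GLPK cannot digest inf."""
    return None if math.isinf(bound) else bound


class LPProblem:
    """An optlang LP mirroring a MetabolicModel (one variable per reaction,
    one steady-state equality per metabolite)."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.lp = optlang.Model(name=model.id)
        try:
            self.lp.configuration.tolerances.feasibility = FEASIBILITY_TOL
        except Exception:  # pragma: no cover - interface-dependent
            pass
        self.variables: Dict[str, optlang.Variable] = {}
        for rid, rxn in model.reactions.items():
            var = optlang.Variable(
                f"v_{len(self.variables)}",
                lb=_finite(rxn.lower_bound),
                ub=_finite(rxn.upper_bound),
            )
            var.reaction_id = rid
            self.variables[rid] = var
        self.lp.add(list(self.variables.values()))
        balances = []
        terms_by_met: Dict[str, list] = {m: [] for m in model.metabolites}
        for rid, rxn in model.reactions.items():
            var = self.variables[rid]
            for mid, coef in rxn.stoichiometry.items():
                terms_by_met[mid].append(coef * var)
        for mid, terms in terms_by_met.items():
            if terms:
                balances.append(
                    optlang.Constraint(sum(terms), lb=0, ub=0, name=f"m_{mid}")
                )
        self.lp.add(balances)
        self._n_extra = 0

    def _expression(self, coefficients: Mapping[str, float]):
        missing = [r for r in coefficients if r not in self.variables]
        if missing:
            raise KeyError(f"objective/fix references unknown reaction(s) {missing}")
        return sum(c * self.variables[r] for r, c in coefficients.items())

    def set_objective(self, coefficients: Mapping[str, float], direction: str = "max"):
        if direction not in ("max", "min"):
            raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
        self.lp.objective = optlang.Objective(
            self._expression(coefficients), direction=direction
        )

    def set_bounds(self, rid: str, lb: float, ub: float) -> None:
        var = self.variables[rid]
        # clear before setting so transient lb > old ub never trips optlang
        var.lb, var.ub = None, None
        var.lb, var.ub = _finite(lb), _finite(ub)

    def add_constraint(self, coefficients: Mapping[str, float],
                       lb: float | None, ub: float | None, name: str | None = None):
        self._n_extra += 1
        cons = optlang.Constraint(
            self._expression(coefficients), lb=lb, ub=ub,
            name=name or f"fix_{self._n_extra}",
        )
        self.lp.add(cons)
        return cons

    def remove_constraint(self, cons) -> None:
        self.lp.remove(cons)

    def optimize(self) -> tuple[str, float | None, Dict[str, float] | None]:
        status = self.lp.optimize()
        if status == "undefined":  # GLPK reports some infeasible LPs this way
            status = INFEASIBLE
        if status == OPTIMAL:
            fluxes = {rid: var.primal for rid, var in self.variables.items()}
            return OPTIMAL, self.lp.objective.value, fluxes
        if status in (INFEASIBLE, UNBOUNDED):
            return status, None, None
        raise SolverError(f"solver returned status {status!r}")


# ---------------------------------------------------------------------------
# Solutions and results


@dataclass
class FluxSolution:
    status: str
    fluxes: Dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None
    stage_optima: list[float] = field(default_factory=list)

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


def steady_state_residual(model: MetabolicModel, fluxes: Mapping[str, float]) -> float:
    """max |S.v| over metabolites; ~0 for any valid steady-state solution."""
    residual = 0.0
    sums: Dict[str, float] = {}
    for rid, rxn in model.reactions.items():
        v = fluxes.get(rid, 0.0)
        for mid, coef in rxn.stoichiometry.items():
            sums[mid] = sums.get(mid, 0.0) + coef * v
    for value in sums.values():
        residual = max(residual, abs(value))
    return residual


@dataclass
class FVAResult:
    minimum: Dict[str, float]
    maximum: Dict[str, float]

    def span(self, rid: str) -> float:
        return self.maximum[rid] - self.minimum[rid]

    def spans(self) -> Dict[str, float]:
        return {rid: self.span(rid) for rid in self.minimum}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"minimum": pd.Series(self.minimum), "maximum": pd.Series(self.maximum)}
        )
        df["span"] = df["maximum"] - df["minimum"]
        df.index.name = "reaction_id"
        return df

    def __iter__(self):
        return iter(self.minimum)


@dataclass
class FluxClassification:
    """Partition of analyzed reactions into zero / fixed / variable flux,
    with loop participants excluded, plus the mean non-zero flux span
    normalized per mmol of carbon input."""

    zero: set[str]
    fixed_nonzero: set[str]
    variable: set[str]
    loops: set[str]
    carbon_input_mmolC: float
    mean_nonzero_span: float
    no_variable_reactions: bool

    @property
    def counts(self) -> dict[str, int]:
        return {
            "zero": len(self.zero),
            "fixed_nonzero": len(self.fixed_nonzero),
            "variable": len(self.variable),
            "loops": len(self.loops),
        }


# ---------------------------------------------------------------------------
# Objective stages / scenarios


@dataclass
class ObjectiveStage:
    """One stage of a lexicographic optimization: optimize, then hold the
    achieved value at ``fraction`` of the optimum before the next stage."""

    coefficients: Dict[str, float]
    direction: str = "max"
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("max", "min"):
            raise ValueError(f"direction must be max/min, got {self.direction!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in (0, 1], got {self.fraction}")


@dataclass
class Scenario:
    """A named simulation setup: bound overrides, an ordered objective
    sequence, carbon sources, and named carbon sinks."""

    name: str
    bounds: Dict[str, tuple[float, float]] = field(default_factory=dict)
    objectives: list[ObjectiveStage] = field(default_factory=list)
    carbon_sources: list[str] = field(default_factory=list)
    sinks: Dict[str, list[str]] = field(default_factory=dict)
    deactivate_tissues: list[str] = field(default_factory=list)
    close_exchanges: bool = False

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "Scenario":
        objectives = [
            ObjectiveStage(
                coefficients=dict(stage["coefficients"]),
                direction=stage.get("direction", "max"),
                fraction=float(stage.get("fraction", 1.0)),
            )
            for stage in raw.get("objectives", [])
        ]
        bounds = {
            rid: (float(lo), float(hi))
            for rid, (lo, hi) in raw.get("bounds", {}).items()
        }
        return cls(
            name=raw.get("name", "scenario"),
            bounds=bounds,
            objectives=objectives,
            carbon_sources=list(raw.get("carbon_sources", [])),
            sinks={k: list(v) for k, v in raw.get("sinks", {}).items()},
            deactivate_tissues=list(raw.get("deactivate_tissues", [])),
            close_exchanges=bool(raw.get("close_exchanges", False)),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "close_exchanges": self.close_exchanges,
            "deactivate_tissues": list(self.deactivate_tissues),
            "bounds": {rid: [lo, hi] for rid, (lo, hi) in self.bounds.items()},
            "objectives": [
                {
                    "coefficients": dict(st.coefficients),
                    "direction": st.direction,
                    "fraction": st.fraction,
                }
                for st in self.objectives
            ],
            "carbon_sources": list(self.carbon_sources),
            "sinks": {k: list(v) for k, v in self.sinks.items()},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def apply_scenario(
    target: MetabolicModel | MultiTissueModel, scenario: Scenario
) -> MetabolicModel:
    """Materialize a scenario as a bounded copy of the underlying model."""
    if isinstance(target, MultiTissueModel):
        mt = (
            target.deactivated(scenario.deactivate_tissues)
            if scenario.deactivate_tissues
            else target
        )
        model = mt.model.copy()
    else:
        model = target.copy()
        for tag in scenario.deactivate_tissues:
            suffix = f"[{tag}]"
            for rxn in model.reactions.values():
                if rxn.id.endswith(suffix):
                    rxn.bounds = (0.0, 0.0)
    if scenario.close_exchanges:
        for rxn in model.reactions.values():
            if rxn.kind is ReactionKind.EXCHANGE:
                rxn.bounds = (0.0, 0.0)
    for rid, (lo, hi) in scenario.bounds.items():
        if rid not in model.reactions:
            raise KeyError(f"scenario {scenario.name!r}: unknown reaction {rid!r}")
        model.reactions[rid].bounds = (lo, hi)
    return model


# ---------------------------------------------------------------------------
# Core operations


def fba(
    model: MetabolicModel,
    objective: Mapping[str, float] | None = None,
    direction: str = "max",
) -> FluxSolution:
    """Flux balance analysis; returns an optimal vertex or a non-optimal status."""
    coeffs = dict(objective) if objective is not None else dict(model.objective)
    if not coeffs:
        raise ValueError("fba needs a non-empty objective")
    lp = LPProblem(model)
    lp.set_objective(coeffs, direction)
    status, value, fluxes = lp.optimize()
    if status != OPTIMAL:
        return FluxSolution(status=status)
    return FluxSolution(status=OPTIMAL, fluxes=fluxes, objective_value=value)


def _fix_band(
    optimum: float, fraction: float, direction: str, band_rel: float = 0.0
) -> tuple[float | None, float | None]:
    """(lb, ub) of the fixing constraint after one lexicographic stage.

    ``band_rel`` relaxes a full fix (fraction 1) by band_rel x max(1, |opt|)
    to rescue numerically infeasible stacked fixes; 0 fixes exactly.
    """
    band = band_rel * max(1.0, abs(optimum))
    if fraction >= 1.0:
        if direction == "max":
            return optimum - band, None
        return None, optimum + band
    if direction == "max":
        if optimum > ZERO_TOL:
            return fraction * optimum, None
        return optimum - (1.0 - fraction) * max(abs(optimum), 1.0), None
    # minimization: hold the achieved value from above
    if optimum < -ZERO_TOL:
        return None, fraction * optimum
    return None, optimum + (1.0 - fraction) * max(abs(optimum), 1.0)


def _normalize_fix(fix) -> ObjectiveStage:
    if isinstance(fix, ObjectiveStage):
        return fix
    coeffs, direction, fraction = fix
    return ObjectiveStage(dict(coeffs), direction, float(fraction))


def _apply_fixes(lp: LPProblem, fixes: Iterable, band_rel: float = 0.0) -> list[float]:
    optima = []
    for i, fix in enumerate(fixes):
        stage = _normalize_fix(fix)
        lp.set_objective(stage.coefficients, stage.direction)
        status, value, _ = lp.optimize()
        if status != OPTIMAL:
            raise InfeasibleScenarioError(
                f"fix stage {i} ({stage.direction} of "
                f"{sorted(stage.coefficients)}) is {status}"
            )
        lb, ub = _fix_band(value, stage.fraction, stage.direction, band_rel)
        lp.add_constraint(stage.coefficients, lb=lb, ub=ub, name=f"stage_{i}")
        optima.append(value)
    return optima


def fva(
    model: MetabolicModel,
    reactions: Iterable[str] | None = None,
    fixes: Sequence | None = None,
    constraints: Sequence[tuple[Mapping[str, float], float | None, float | None]]
    | None = None,
) -> FVAResult:
    """Per-reaction flux minimum/maximum over the (optionally fixed) space.

    ``fixes`` are optimize-then-hold stages (see :class:`ObjectiveStage`);
    ``constraints`` are plain linear constraints ``(coefficients, lb, ub)``
    added verbatim.
    """
    rids = list(reactions) if reactions is not None else list(model.reactions)
    unknown = [r for r in rids if r not in model.reactions]
    if unknown:
        raise KeyError(f"fva: unknown reaction(s) {unknown}")

    def run(band_rel: float) -> FVAResult:
        lp = LPProblem(model)
        for coeffs, lo, hi in constraints or ():
            lp.add_constraint(coeffs, lb=lo, ub=hi)
        _apply_fixes(lp, fixes or (), band_rel)
        minimum: Dict[str, float] = {}
        maximum: Dict[str, float] = {}
        for rid in rids:
            lp.set_objective({rid: 1.0}, "min")
            status, value, _ = lp.optimize()
            if status == UNBOUNDED:
                value = -math.inf
            elif status != OPTIMAL:
                raise InfeasibleScenarioError(
                    f"fva: model {status} when probing {rid}"
                )
            minimum[rid] = value
            lp.set_objective({rid: 1.0}, "max")
            status, value, _ = lp.optimize()
            if status == UNBOUNDED:
                value = math.inf
            elif status != OPTIMAL:
                raise InfeasibleScenarioError(
                    f"fva: model {status} when probing {rid}"
                )
            maximum[rid] = value
        return FVAResult(minimum=minimum, maximum=maximum)

    try:
        return run(0.0)
    except InfeasibleScenarioError:
        if not fixes:
            raise
        # exact stacked fixes can be numerically infeasible; relax by the
        # standard tolerance band and retry before giving up
        return run(ZERO_TOL)


def detect_loops(model: MetabolicModel, tol: float = ZERO_TOL) -> set[str]:
    """Reactions able to carry flux with every exchange closed.

    All exchange-kind reactions are bounded to zero and forced fluxes
    (positive lower bounds, e.g. maintenance demands) are relaxed; any
    reaction whose closed-system FVA range strays from zero participates
    in a thermodynamically infeasible internal loop.
    """
    closed = model.copy()
    for rxn in closed.reactions.values():
        if rxn.kind is ReactionKind.EXCHANGE:
            rxn.bounds = (0.0, 0.0)
        else:
            rxn.bounds = (min(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0))
    result = fva(closed)
    return {
        rid
        for rid in result.minimum
        if abs(result.minimum[rid]) >= tol or abs(result.maximum[rid]) >= tol
    }


def classify(
    fva_result: FVAResult,
    loop_set: Iterable[str],
    carbon_input_mmolC: float,
    tol: float = ZERO_TOL,
) -> FluxClassification:
    """Zero / fixed / variable partition and mean-span metric.

    A zero-flux reaction has span < tol and both extrema within tol of
    zero; a fixed reaction has span < tol but a non-zero value; the rest
    are variable.  Loop participants are excluded from the partition and
    from the mean span, which averages span / carbon input (mmol C) over
    variable reactions.
    """
    if carbon_input_mmolC <= 0:
        raise ValueError("carbon_input_mmolC must be positive")
    loop_set = set(loop_set)
    missing = [r for r in loop_set if r not in fva_result.minimum]
    if missing:
        raise KeyError(f"loop reactions missing from FVA result: {missing}")
    zero: set[str] = set()
    fixed: set[str] = set()
    variable: set[str] = set()
    spans = []
    for rid in fva_result.minimum:
        if rid in loop_set:
            continue
        lo, hi = fva_result.minimum[rid], fva_result.maximum[rid]
        span = hi - lo
        if span < tol:
            if abs(lo) < tol and abs(hi) < tol:
                zero.add(rid)
            else:
                fixed.add(rid)
        else:
            variable.add(rid)
            spans.append(span / carbon_input_mmolC)
    empty = not spans
    return FluxClassification(
        zero=zero,
        fixed_nonzero=fixed,
        variable=variable,
        loops=loop_set,
        carbon_input_mmolC=carbon_input_mmolC,
        mean_nonzero_span=0.0 if empty else float(np.mean(spans)),
        no_variable_reactions=empty,
    )


def lexicographic_fba(model: MetabolicModel, scenario: Scenario) -> FluxSolution:
    """Optimize the scenario's objectives in order, fixing each achieved
    value (at its stage fraction) before the next; returns the final
    solution with all stage optima recorded."""
    if not scenario.objectives:
        raise ValueError(f"scenario {scenario.name!r} has no objectives")

    def run(band_rel: float) -> FluxSolution:
        lp = LPProblem(model)
        optima: list[float] = []
        for i, stage in enumerate(scenario.objectives):
            lp.set_objective(stage.coefficients, stage.direction)
            status, value, fluxes = lp.optimize()
            if status != OPTIMAL:
                raise InfeasibleScenarioError(
                    f"scenario {scenario.name!r}: stage {i} "
                    f"({stage.direction} of {sorted(stage.coefficients)}) "
                    f"is {status}"
                )
            optima.append(value)
            if i < len(scenario.objectives) - 1:
                lb, ub = _fix_band(value, stage.fraction, stage.direction, band_rel)
                lp.add_constraint(stage.coefficients, lb=lb, ub=ub, name=f"stage_{i}")
        return FluxSolution(
            status=OPTIMAL,
            fluxes=fluxes,
            objective_value=optima[-1],
            stage_optima=optima,
        )

    try:
        return run(0.0)
    except InfeasibleScenarioError:
        if len(scenario.objectives) == 1:
            raise
        return run(ZERO_TOL)


def _reaction_net_carbon(model: MetabolicModel, rid: str) -> float:
    """mmol C destroyed (removed from the system) per unit flux."""
    rxn = model.reactions[rid]
    net = 0.0
    for mid, coef in rxn.stoichiometry.items():
        met = model.metabolites[mid]
        n_c = met.carbon_count()
        if n_c is None:
            raise ValueError(
                f"carbon accounting: metabolite {mid!r} (reaction {rid!r}) "
                "has no formula"
            )
        net -= coef * n_c
    return net


def carbon_input(
    model: MetabolicModel,
    solution: FluxSolution,
    source_exchanges: Iterable[str],
) -> float:
    """Total carbon entering through the source exchanges, in mmol C/h."""
    total = 0.0
    for rid in source_exchanges:
        per_flux = _reaction_net_carbon(model, rid)
        v = solution.fluxes[rid]
        # uptake: negative exchange flux creates carbon in the system
        total += max(-v * per_flux, 0.0)
    return total


def carbon_split(
    model: MetabolicModel,
    solution: FluxSolution,
    source_exchanges: Iterable[str],
    sinks: Mapping[str, Iterable[str]],
) -> Dict[str, float]:
    """Fraction of input carbon reaching each named sink group.

    Sinks are groups of carbon-removing reactions (secretion exchanges or
    storage drains).  The remainder is reported under ``maintenance``.
    Fractions sum to 1 within 1e-6.
    """
    if not solution.optimal:
        raise ValueError("carbon_split requires an optimal solution")
    total_in = carbon_input(model, solution, source_exchanges)
    if total_in <= ZERO_TOL:
        raise ValueError("zero carbon input: the split is undefined")
    out: Dict[str, float] = {}
    named = 0.0
    for name, rids in sinks.items():
        carbon = 0.0
        for rid in rids:
            per_flux = _reaction_net_carbon(model, rid)
            carbon += max(solution.fluxes[rid] * per_flux, 0.0)
        frac = carbon / total_in
        out[name] = frac
        named += frac
    out["maintenance"] = 1.0 - named
    return out
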
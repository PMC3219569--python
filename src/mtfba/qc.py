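"""Model quality control: futile-cycle tests, dead-end detection, and
media-based functional validation tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model_core import (
    MetabolicModel,
    ModelConsistencyError,
    Reaction,
    ReactionKind,
)
from .simulate import OPTIMAL, UNBOUNDED, ZERO_TOL, detect_loops, fba

FEASIBLE_POSITIVE = "feasible_positive"
ZERO = "zero"


@dataclass
class FunctionTest:
    """One functional validation: apply a medium, maximize a target,
    compare against the expectation.

    ``target`` is either an objective map (reaction id -> coefficient) or
    a metabolite id, for which a temporary demand drain is synthesized.
    ``medium`` overrides exchange bounds; all other exchanges are closed
    first unless ``close_other_exchanges`` is False.
    """

    name: str
    target: Mapping[str, float] | str
    medium: Dict[str, tuple[float, float]] = field(default_factory=dict)
    expectation: str = FEASIBLE_POSITIVE
    close_other_exchanges: bool = True

    def __post_init__(self) -> None:
        if self.expectation not in (FEASIBLE_POSITIVE, ZERO):
            raise ValueError(f"unknown expectation {self.expectation!r}")


@dataclass
class TestOutcome:
    name: str
    passed: bool
    measured: float | None
    status: str  # pass/fail/error
    witnesses: list[str] = field(default_factory=list)
    message: str = ""


@dataclass
class QCReport:
    outcomes: list[TestOutcome]

    @property
    def passed(self) -> bool:
        return all(o.passed for o in self.outcomes)

    def failures(self) -> list[TestOutcome]:
        return [o for o in self.outcomes if not o.passed]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "test": o.name,
                    "status": o.status,
                    "measured": o.measured,
                    "witnesses": ";".join(o.witnesses),
                    "message": o.message,
                }
                for o in self.outcomes
            ]
        )


def _closed_copy(model: MetabolicModel) -> MetabolicModel:
    closed = model.copy()
    for rxn in closed.reactions.values():
        if rxn.kind is ReactionKind.EXCHANGE:
            rxn.bounds = (0.0, 0.0)
        else:
            rxn.bounds = (min(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0))
    return closed


def energy_cycle_test(
    model: MetabolicModel,
    energy_drains: Sequence[str],
    tol: float = ZERO_TOL,
) -> QCReport:
    """With all exchanges closed, no energy drain may run.

    Maximizes each drain in the closed system; any positive or unbounded
    optimum is a thermodynamically impossible closed-system energy yield
    and fails with the participating loop reactions as witnesses.
    """
    outcomes: list[TestOutcome] = []
    if not energy_drains:
        return QCReport(
            [
                TestOutcome(
                    name="energy_cycle(vacuous)",
                    passed=True,
                    measured=None,
                    status="pass",
                    message="warning: no energy drains listed; vacuous pass",
                )
            ]
        )
    closed = _closed_copy(model)
    for drain in energy_drains:
        if drain not in closed.reactions:
            outcomes.append(
                TestOutcome(
                    name=f"energy_cycle({drain})",
                    passed=False,
                    measured=None,
                    status="error",
                    message=f"unknown energy drain reaction {drain!r}",
                )
            )
            continue
        # the drain itself must be allowed to run in the closed system
        rxn = closed.reactions[drain]
        original = model.reactions[drain]
        rxn.bounds = (min(original.lower_bound, 0.0), original.upper_bound)
        solution = fba(closed, {drain: 1.0}, "max")
        rxn.bounds = (min(original.lower_bound, 0.0), max(original.upper_bound, 0.0))
        if solution.status == UNBOUNDED:
            witnesses = sorted(detect_loops(model))
            outcomes.append(
                TestOutcome(
                    name=f"energy_cycle({drain})",
                    passed=False,
                    measured=float("inf"),
                    status="fail",
                    witnesses=witnesses,
                    message="drain unbounded with closed exchanges",
                )
            )
            continue
        value = solution.objective_value if solution.status == OPTIMAL else 0.0
        ok = solution.status == OPTIMAL and value <= tol
        outcomes.append(
            TestOutcome(
                name=f"energy_cycle({drain})",
                passed=ok,
                measured=value,
                status="pass" if ok else "fail",
                witnesses=[] if ok else sorted(detect_loops(model)),
                message="" if ok else "positive closed-system energy yield",
            )
        )
    return QCReport(outcomes)


def dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that can only be produced or only consumed.

    Reversibility counts: a reversible reaction can both make and take a
    metabolite.  Exchange reactions count as producers/consumers, so a
    species with an open exchange is never a dead end.
    """
    can_produce: set[str] = set()
    can_consume: set[str] = set()
    for rxn in model.reactions.values():
        forward = rxn.upper_bound > 0
        backward = rxn.lower_bound < 0
        for mid, coef in rxn.stoichiometry.items():
            if coef > 0:
                if forward:
                    can_produce.add(mid)
                if backward:
                    can_consume.add(mid)
            else:
                if forward:
                    can_consume.add(mid)
                if backward:
                    can_produce.add(mid)
    return {
        mid
        for mid in model.metabolites
        if not (mid in can_produce and mid in can_consume)
    }


def _with_demand(model: MetabolicModel, met_id: str) -> tuple[MetabolicModel, str]:
    if met_id not in model.metabolites:
        raise ModelConsistencyError(f"unknown metabolite {met_id!r}")
    demand_id = f"DM_{met_id}"
    work = model.copy()
    if demand_id not in work.reactions:
        work.add_reaction(
            Reaction(
                id=demand_id,
                stoichiometry={met_id: -1.0},
                lower_bound=0.0,
                upper_bound=1e6,
                kind=ReactionKind.BIOMASS,  # a drain, exempt from balance
                name=f"temporary demand for {met_id}",
            )
        )
    return work, demand_id


def run_function_tests(
    model: MetabolicModel,
    suite: Sequence[FunctionTest],
    tol: float = ZERO_TOL,
) -> QCReport:
    """Run media-based functional tests against a model."""
    if not suite:
        raise ValueError("run_function_tests: empty suite")
    outcomes: list[TestOutcome] = []
    for test in suite:
        try:
            if isinstance(test.target, str):
                work, demand_id = _with_demand(model, test.target)
                objective: Mapping[str, float] = {demand_id: 1.0}
            else:
                work = model.copy()
                unknown = [r for r in test.target if r not in work.reactions]
                if unknown:
                    raise ModelConsistencyError(
                        f"unknown target reaction(s) {unknown}"
                    )
                objective = dict(test.target)
        except ModelConsistencyError as exc:
            outcomes.append(
                TestOutcome(
                    name=test.name, passed=False, measured=None,
                    status="error", message=str(exc),
                )
            )
            continue
        if test.close_other_exchanges:
            for rxn in work.reactions.values():
                if rxn.kind is ReactionKind.EXCHANGE and rxn.id not in test.medium:
                    rxn.bounds = (0.0, 0.0)
        bad_medium = [rid for rid in test.medium if rid not in work.reactions]
        if bad_medium:
            outcomes.append(
                TestOutcome(
                    name=test.name, passed=False, measured=None, status="error",
                    message=f"unknown medium reaction(s) {bad_medium}",
                )
            )
            continue
        for rid, (lo, hi) in test.medium.items():
            work.reactions[rid].bounds = (lo, hi)
        solution = fba(work, objective, "max")
        if solution.status == UNBOUNDED:
            measured, status_ok = float("inf"), test.expectation == FEASIBLE_POSITIVE
        elif solution.status != OPTIMAL:
            measured, status_ok = None, False
        else:
            measured = solution.objective_value
            if test.expectation == FEASIBLE_POSITIVE:
                status_ok = measured > tol
            else:
                status_ok = abs(measured) <= tol
        outcomes.append(
            TestOutcome(
                name=test.name,
                passed=status_ok,
                measured=measured,
                status="pass" if status_ok else "fail",
                message="" if status_ok else f"expected {test.expectation}",
            )
        )
    return QCReport(outcomes)


def load_suite(path) -> list[FunctionTest]:
    """Load a YAML list of function tests.

    Each entry: ``name``, ``target`` (objective map or metabolite id),
    optional ``medium`` (exchange id -> [lb, ub]), ``expectation``, and
    ``close_other_exchanges``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    suite = []
    for entry in raw:
        medium = {
            rid: (float(lo), float(hi))
            for rid, (lo, hi) in entry.get("medium", {}).items()
        }
        target = entry["target"]
        if isinstance(target, Mapping):
            target = {str(k): float(v) for k, v in target.items()}
        suite.append(
            FunctionTest(
                name=entry["name"],
                target=target,
                medium=medium,
                expectation=entry.get("expectation", FEASIBLE_POSITIVE),
                close_other_exchanges=entry.get("close_other_exchanges", True),
            )
        )
    return suite
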
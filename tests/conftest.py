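"""Shared fixtures: toy tissue models, merged models, and micro-models
(diamond, chain) used across the suite."""

from __future__ import annotations

import pytest

from mtfba.fixtures import (
    ToyScenario,
    toy_multitissue,
    toy_tissue,
)
from mtfba.model_core import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
)


@pytest.fixture()
def params() -> ToyScenario:
    return ToyScenario()


@pytest.fixture()
def liver(params):
    return toy_tissue("liver", params)


@pytest.fixture()
def muscle(params):
    return toy_tissue("muscle", params)


@pytest.fixture()
def fat(params):
    return toy_tissue("fat", params)


@pytest.fixture()
def mt(params):
    return toy_multitissue(params)


def build_model(reactions, metabolites=None, model_id="micro", objective=None):
    """Construct a model from (id, stoich, lb, ub, kind) tuples; metabolites
    are created on the fly (optionally with (formula, charge) from the
    ``metabolites`` map)."""
    model = MetabolicModel(model_id)
    metabolites = metabolites or {}
    for rid, stoich, lb, ub, kind in reactions:
        for met_id in stoich:
            if met_id not in model.metabolites:
                formula, charge = metabolites.get(met_id, (None, None))
                model.add_metabolite(
                    Metabolite(id=met_id, formula=formula, charge=charge)
                )
        model.add_reaction(
            Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb,
                     upper_bound=ub, kind=ReactionKind(kind))
        )
    if objective:
        model.set_objective(objective)
    return model


@pytest.fixture()
def diamond():
    """A uptake fixed at 10; A->B via r1 or r2; B export.

    A carries 3 carbons so the default carbon input is 30 mmol C.
    """
    return build_model(
        [
            ("EX_A", {"A[c]": -1.0}, -10.0, -10.0, "exchange"),
            ("r1", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0, "internal"),
            ("r2", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0, "internal"),
            ("EX_B", {"B[c]": -1.0}, 0.0, 1000.0, "exchange"),
        ],
        metabolites={"A[c]": ("C3H6O3", 0), "B[c]": ("C3H6O3", 0)},
        model_id="diamond",
        objective={"EX_B": 1.0},
    )


@pytest.fixture()
def chain():
    """Linear chain with uptake fixed at 5: every flux is determined."""
    return build_model(
        [
            ("EX_A", {"A[c]": -1.0}, -5.0, -5.0, "exchange"),
            ("r1", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, 1000.0, "internal"),
            ("r2", {"B[c]": -1.0, "C[c]": 1.0}, 0.0, 1000.0, "internal"),
            ("EX_C", {"C[c]": -1.0}, 0.0, 1000.0, "exchange"),
        ],
        model_id="chain",
        objective={"EX_C": 1.0},
    )
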
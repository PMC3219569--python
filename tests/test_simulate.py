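"""Tests for FBA, FVA, classification, loop detection, lexicographic
optimization, and carbon accounting — cross-checked against brute-force
vertex enumeration oracles."""

import math

import pytest

from mtfba.fixtures import (
    ToyScenario,
    absorptive_scenario,
    alanine_scenario,
    cori_scenario,
    manifest,
    toy_multitissue,
)
from mtfba.model_core import Metabolite, Reaction, ReactionKind
from mtfba.simulate import (
    InfeasibleScenarioError,
    ObjectiveStage,
    Scenario,
    apply_scenario,
    carbon_input,
    carbon_split,
    classify,
    detect_loops,
    fba,
    fva,
    lexicographic_fba,
    steady_state_residual,
)

from conftest import build_model
from _oracles import fba_by_vertex_enumeration, fva_by_vertex_enumeration

# after fixing an objective at its optimum the residual fix band can leak
# into spans; classify with a tolerance above that leakage
CLASS_TOL = 1e-4


def toy_cori_liver():
    """The hand-LP toy: lactate 6 in, glucose synthesis 2 lac + 6 atp,
    oxidation lac + 3 o2 -> 15 atp, maintenance >= 30.

    Vertex derivation: 2x + y = 6 and 15y - 6x >= 30 give x <= 5/3.
    """
    return build_model(
        [
            ("EX_lac", {"lac[e]": -1.0}, -6.0, -6.0, "exchange"),
            ("EX_glc", {"glc[e]": -1.0}, 0.0, 1000.0, "exchange"),
            ("EX_o2", {"o2[e]": -1.0}, -1000.0, 0.0, "exchange"),
            ("GNG", {"lac[e]": -2.0, "atp[c]": -6.0, "glc[e]": 1.0,
                     "adp[c]": 6.0}, 0.0, 1000.0, "internal"),
            ("LACOX", {"lac[e]": -1.0, "o2[e]": -3.0, "adp[c]": -15.0,
                       "atp[c]": 15.0}, 0.0, 1000.0, "internal"),
            ("ATPM", {"atp[c]": -1.0, "adp[c]": 1.0}, 30.0, 1000.0, "internal"),
        ],
        metabolites={
            "lac[e]": ("C3H5O3", -1), "glc[e]": ("C6H12O6", 0),
            "o2[e]": ("O2", 0), "atp[c]": (None, None), "adp[c]": (None, None),
        },
        model_id="toy_cori_liver",
        objective={"EX_glc": 1.0},
    )


class TestFBA:
    def test_closed_system_yields_zero(self, diamond):
        for rxn in diamond.exchanges:
            rxn.bounds = (0.0, 0.0)
        sol = fba(diamond, {"r1": 1.0})
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_toy_cori_hand_lp(self):
        sol = fba(toy_cori_liver(), {"EX_glc": 1.0})
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(5.0 / 3.0, abs=1e-6)

    def test_toy_cori_against_vertex_oracle(self):
        model = toy_cori_liver()
        oracle = fba_by_vertex_enumeration(model, {"EX_glc": 1.0})
        sol = fba(model, {"EX_glc": 1.0})
        assert sol.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_steady_state_invariant(self, mt, params):
        scen = cori_scenario(params)
        model = apply_scenario(mt, scen)
        sol = fba(model, {"EX_glc[bl]": 1.0})
        assert sol.status == "optimal"
        assert steady_state_residual(model, sol.fluxes) <= 1e-6

    def test_fluxes_within_bounds(self, mt, params):
        model = apply_scenario(mt, cori_scenario(params))
        sol = fba(model, {"EX_glc[bl]": 1.0})
        for rid, v in sol.fluxes.items():
            rxn = model.reactions[rid]
            assert rxn.lower_bound - 1e-6 <= v <= rxn.upper_bound + 1e-6

    def test_infeasible_status(self, chain):
        chain.reactions["EX_C"].bounds = (0.0, 0.0)
        sol = fba(chain, {"r1": 1.0})
        assert sol.status == "infeasible"

    def test_unbounded_status(self):
        # two free parallel routes form an unbounded internal cycle
        model = build_model(
            [
                ("r1", {"a[c]": -1.0, "b[c]": 1.0}, -math.inf, math.inf,
                 "internal"),
                ("r2", {"a[c]": -1.0, "b[c]": 1.0}, -math.inf, math.inf,
                 "internal"),
            ]
        )
        assert fba(model, {"r1": 1.0}).status == "unbounded"

    def test_empty_objective_rejected(self, chain):
        chain.set_objective({})
        with pytest.raises(ValueError):
            fba(chain)

    def test_lp_homogeneity(self):
        """Scaling all bounds by k > 0 scales the optimum by k."""
        model = toy_cori_liver()
        base = fba(model, {"EX_glc": 1.0}).objective_value
        for k in (0.5, 2.0, 7.0):
            scaled = model.copy()
            for rxn in scaled.reactions.values():
                rxn.bounds = (k * rxn.lower_bound, k * rxn.upper_bound)
            value = fba(scaled, {"EX_glc": 1.0}).objective_value
            assert value == pytest.approx(k * base, rel=1e-6)


class TestFVA:
    def test_diamond_matches_vertex_enumeration(self, diamond):
        result = fva(diamond)
        lo, hi = fva_by_vertex_enumeration(diamond)
        for rid in diamond.reactions:
            assert result.minimum[rid] == pytest.approx(lo[rid], abs=1e-6)
            assert result.maximum[rid] == pytest.approx(hi[rid], abs=1e-6)
        assert result.minimum["r1"] == pytest.approx(0.0, abs=1e-6)
        assert result.maximum["r1"] == pytest.approx(10.0, abs=1e-6)
        assert result.span("r1") == pytest.approx(10.0, abs=1e-6)

    def test_chain_fully_determined(self, chain):
        result = fva(chain)
        for rid in chain.reactions:
            assert abs(result.minimum[rid]) == pytest.approx(5.0, abs=1e-6)
            assert result.span(rid) == pytest.approx(0.0, abs=1e-6)

    def test_toy_cori_matches_vertex_enumeration(self):
        model = toy_cori_liver()
        result = fva(model)
        lo, hi = fva_by_vertex_enumeration(model)
        for rid in model.reactions:
            assert result.minimum[rid] == pytest.approx(lo[rid], abs=1e-6)
            assert result.maximum[rid] == pytest.approx(hi[rid], abs=1e-6)

    def test_objective_fixed_at_optimum_has_zero_span(self, diamond):
        result = fva(
            diamond, reactions=["EX_B"],
            fixes=[ObjectiveStage({"EX_B": 1.0}, "max", 1.0)],
        )
        assert result.minimum["EX_B"] == pytest.approx(10.0, abs=1e-5)
        assert result.span("EX_B") == pytest.approx(0.0, abs=1e-5)

    def test_sandwich_property(self, mt, params):
        """Any feasible solution lies within the FVA ranges computed
        under the same fixes."""
        scen = cori_scenario(params)
        model = apply_scenario(mt, scen)
        sol = lexicographic_fba(model, scen)
        result = fva(model, fixes=scen.objectives)
        for rid, v in sol.fluxes.items():
            assert result.minimum[rid] - 1e-5 <= v <= result.maximum[rid] + 1e-5

    def test_infeasible_fix_names_stage(self, chain):
        chain.reactions["EX_C"].bounds = (0.0, 0.0)
        with pytest.raises(InfeasibleScenarioError, match="stage 0"):
            fva(chain, fixes=[ObjectiveStage({"r1": 1.0}, "max", 1.0)])

    def test_unknown_reaction_rejected(self, chain):
        with pytest.raises(KeyError):
            fva(chain, reactions=["ghost"])


class TestDetectLoops:
    def test_loop_free_toy(self, mt):
        assert detect_loops(mt.model) == set()

    def test_injected_three_cycle_flagged(self, mt):
        model = mt.model.copy()
        for mid in ("la[h_c]", "lb[h_c]", "lc[h_c]"):
            model.add_metabolite(Metabolite(id=mid))
        for rid, (src, dst) in {
            "L1[h]": ("la[h_c]", "lb[h_c]"),
            "L2[h]": ("lb[h_c]", "lc[h_c]"),
            "L3[h]": ("lc[h_c]", "la[h_c]"),
        }.items():
            model.add_reaction(
                Reaction(id=rid, stoichiometry={src: -1.0, dst: 1.0},
                         lower_bound=-1000.0, upper_bound=1000.0)
            )
        assert detect_loops(model) == {"L1[h]", "L2[h]", "L3[h]"}

    def test_forced_fluxes_relaxed(self, mt, params):
        """Positive maintenance lower bounds must not masquerade as loops."""
        model = apply_scenario(mt, cori_scenario(params))
        assert model.reactions["ATPM[h]"].lower_bound > 0
        assert detect_loops(model) == set()


class TestClassify:
    def test_diamond_mean_span(self, diamond):
        """A is a 3-carbon species at uptake 10 -> 30 mmol C input;
        r1/r2 spans are 10 -> mean non-zero span 10/30."""
        result = fva(diamond)
        cls = classify(result, set(), 30.0)
        assert cls.variable == {"r1", "r2"}
        assert cls.mean_nonzero_span == pytest.approx(10.0 / 30.0, abs=1e-9)
        assert not cls.no_variable_reactions

    def test_all_fixed_chain_flags_empty_mean(self, chain):
        result = fva(chain)
        cls = classify(result, set(), 15.0)
        assert cls.variable == set()
        assert cls.mean_nonzero_span == 0.0
        assert cls.no_variable_reactions
        assert cls.fixed_nonzero == set(chain.reactions)

    def test_zero_vs_fixed_separation(self, diamond):
        diamond.reactions["r2"].bounds = (0.0, 0.0)
        result = fva(diamond)
        cls = classify(result, set(), 30.0)
        assert cls.zero == {"r2"}
        assert cls.fixed_nonzero == {"EX_A", "r1", "EX_B"}

    def test_loop_exclusion_and_partition(self, diamond):
        result = fva(diamond)
        cls = classify(result, {"r2"}, 30.0)
        assert cls.variable == {"r1"}
        analyzed = cls.zero | cls.fixed_nonzero | cls.variable | cls.loops
        assert analyzed == set(diamond.reactions)
        assert sum(cls.counts.values()) == len(diamond.reactions)

    def test_missing_loop_reaction_rejected(self, diamond):
        result = fva(diamond, reactions=["r1"])
        with pytest.raises(KeyError):
            classify(result, {"ghost"}, 30.0)

    def test_nonpositive_carbon_rejected(self, diamond):
        result = fva(diamond)
        with pytest.raises(ValueError):
            classify(result, set(), 0.0)


class TestLexicographic:
    def test_single_objective_reduces_to_fba(self, diamond):
        scen = Scenario(name="one",
                        objectives=[ObjectiveStage({"EX_B": 1.0}, "max", 1.0)])
        lexi = lexicographic_fba(diamond, scen)
        plain = fba(diamond, {"EX_B": 1.0})
        assert lexi.objective_value == pytest.approx(plain.objective_value, 1e-9)

    def test_order_decides_on_shared_substrate(self):
        """Two objectives competing for one substrate: the first stage
        takes everything."""
        def competing():
            return build_model(
                [
                    ("EX_A", {"A[c]": -1.0}, -10.0, 0.0, "exchange"),
                    ("obj1", {"A[c]": -1.0}, 0.0, 1000.0, "internal"),
                    ("obj2", {"A[c]": -1.0}, 0.0, 1000.0, "internal"),
                ]
            )

        forward = Scenario(name="fwd", objectives=[
            ObjectiveStage({"obj1": 1.0}, "max", 1.0),
            ObjectiveStage({"obj2": 1.0}, "max", 1.0),
        ])
        sol = lexicographic_fba(competing(), forward)
        assert sol.stage_optima[0] == pytest.approx(10.0, abs=1e-6)
        assert sol.stage_optima[1] == pytest.approx(0.0, abs=1e-6)
        backward = Scenario(name="bwd", objectives=[
            ObjectiveStage({"obj2": 1.0}, "max", 1.0),
            ObjectiveStage({"obj1": 1.0}, "max", 1.0),
        ])
        sol = lexicographic_fba(competing(), backward)
        assert sol.stage_optima[0] == pytest.approx(10.0, abs=1e-6)
        assert sol.stage_optima[1] == pytest.approx(0.0, abs=1e-6)

    def test_fraction_releases_substrate(self):
        model = build_model(
            [
                ("EX_A", {"A[c]": -1.0}, -10.0, 0.0, "exchange"),
                ("obj1", {"A[c]": -1.0}, 0.0, 1000.0, "internal"),
                ("obj2", {"A[c]": -1.0}, 0.0, 1000.0, "internal"),
            ]
        )
        scen = Scenario(name="fraction", objectives=[
            ObjectiveStage({"obj1": 1.0}, "max", 0.8),
            ObjectiveStage({"obj2": 1.0}, "max", 1.0),
        ])
        sol = lexicographic_fba(model, scen)
        assert sol.stage_optima[1] == pytest.approx(2.0, abs=1e-6)

    def test_absorptive_stage_ordering(self, mt, params):
        """Fat storage first, then glycogen: both stage optima match the
        closed forms."""
        scen = absorptive_scenario(params)
        model = apply_scenario(mt, scen)
        sol = lexicographic_fba(model, scen)
        expected = manifest(params)["absorptive"]
        assert sol.stage_optima[0] == pytest.approx(
            expected["triacylglycerol_optimum"], abs=1e-6
        )
        assert sol.stage_optima[1] == pytest.approx(
            expected["glycogen_optimum"], abs=1e-6
        )

    def test_no_objectives_rejected(self, diamond):
        with pytest.raises(ValueError):
            lexicographic_fba(diamond, Scenario(name="empty"))


class TestCarbonSplit:
    def test_total_conversion(self):
        model = build_model(
            [
                ("EX_A", {"A[e]": -1.0}, -5.0, 0.0, "exchange"),
                ("r", {"A[e]": -1.0, "B[e]": 1.0}, 0.0, 1000.0, "internal"),
                ("EX_B", {"B[e]": -1.0}, 0.0, 1000.0, "exchange"),
            ],
            metabolites={"A[e]": ("C6H12O6", 0), "B[e]": ("C6H12O6", 0)},
        )
        sol = fba(model, {"EX_B": 1.0})
        split = carbon_split(model, sol, ["EX_A"], {"B": ["EX_B"]})
        assert split["B"] == pytest.approx(1.0, abs=1e-6)
        assert split["maintenance"] == pytest.approx(0.0, abs=1e-6)

    def test_toy_cori_split(self):
        """Glucose 5/3 x 6 C = 10 C of 18 C input -> 0.556 / 0.444."""
        model = toy_cori_liver()
        sol = fba(model, {"EX_glc": 1.0})
        split = carbon_split(model, sol, ["EX_lac"], {"glucose": ["EX_glc"]})
        assert split["glucose"] == pytest.approx(10.0 / 18.0, abs=1e-6)
        assert split["maintenance"] == pytest.approx(8.0 / 18.0, abs=1e-6)

    def test_fractions_sum_to_one(self, mt, params):
        scen = alanine_scenario(params)
        model = apply_scenario(mt, scen)
        sol = lexicographic_fba(model, scen)
        split = carbon_split(model, sol, scen.carbon_sources, scen.sinks)
        assert sum(split.values()) == pytest.approx(1.0, abs=1e-6)

    def test_zero_carbon_input_rejected(self, diamond):
        diamond.reactions["EX_A"].bounds = (0.0, 0.0)
        sol = fba(diamond, {"EX_B": 1.0})
        with pytest.raises(ValueError, match="zero carbon"):
            carbon_split(diamond, sol, ["EX_A"], {"B": ["EX_B"]})

    def test_missing_formula_rejected(self, chain):
        sol = fba(chain, {"EX_C": 1.0})
        with pytest.raises(ValueError, match="formula"):
            carbon_split(chain, sol, ["EX_A"], {"C": ["EX_C"]})


class TestIntegrationConstrains:
    def test_integrated_spans_never_exceed_individual(self, params):
        """Adding tissues to a nutrient-limited scenario never increases a
        shared reaction's span (solution-space shrinkage)."""
        mt = toy_multitissue(params)
        scen = cori_scenario(params)
        integrated = apply_scenario(mt, scen)
        hepatic = [rid for rid, (t, _) in mt.provenance.items() if t == "h"]
        res_int = fva(integrated, reactions=hepatic)

        # individual liver: other tissues inactivated, every extra-system
        # exchange opened (as individual-tissue simulations require); any
        # integrated hepatic flux pattern stays feasible because the open
        # exchanges absorb what the other tissues contributed to the blood
        individual = apply_scenario(mt.deactivated(["m", "a"]), scen)
        for rxn in individual.exchanges:
            rxn.bounds = (-params.bound, params.bound)
        res_ind = fva(individual, reactions=hepatic)

        assert any(res_ind.span(r) > res_int.span(r) + 1e-3 for r in hepatic)
        for rid in hepatic:
            assert res_int.span(rid) <= res_ind.span(rid) + 1e-5

    def test_multi_tissue_scenario_classification(self, mt, params):
        scen = cori_scenario(params)
        model = apply_scenario(mt, scen)
        sol = lexicographic_fba(model, scen)
        loops = detect_loops(model)
        result = fva(model, fixes=scen.objectives)
        total_c = carbon_input(model, sol, scen.carbon_sources)
        assert total_c == pytest.approx(18.0, abs=1e-6)
        cls = classify(result, loops, total_c, tol=CLASS_TOL)
        # the two-tissue cycle at fixed optimum is fully determined
        assert cls.variable == set()
        assert cls.no_variable_reactions
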
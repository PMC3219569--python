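"""Tests for consensus calling, GIMME extraction, differential activity,
and call-stability analysis."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtfba.context import (
    ExpressionCallSet,
    ExpressionDataError,
    GeneStateSet,
    call_stability,
    consensus_states,
    differential_activity,
    gimme_extract,
    reaction_states,
)
from mtfba.fixtures import (
    ESSENTIAL_GENE,
    REDUNDANT_GENE,
    starvation_scenario,
    toy_expression,
    toy_multitissue,
)
from mtfba.integrate import wrap_multitissue
from mtfba.simulate import InfeasibleScenarioError, apply_scenario, fba

from conftest import build_model


def calls_from_rows(rows):
    calls = ExpressionCallSet()
    for tissue, group, sample, gene, call in rows:
        calls.add_call(tissue, group, sample, gene, call)
    return calls


@pytest.fixture()
def starved(params):
    """The merged toy under the starvation scenario, with its RMF."""
    mt = toy_multitissue(params)
    scen = starvation_scenario(params)
    bounded = wrap_multitissue(apply_scenario(mt, scen))
    return bounded, scen.objectives[0].coefficients


def group_states(mt, calls, group):
    states = GeneStateSet()
    for tissue, g in calls.groups():
        if g == group:
            states.update(consensus_states(calls, tissue, group))
    return states


class TestConsensus:
    def test_unanimous_present(self):
        calls = calls_from_rows(
            [("h", "g1", f"s{i}", "g1gene", "P") for i in range(3)]
        )
        states = consensus_states(calls, "h", "g1")
        assert states.tissue_states("h") == {"g1gene": True}

    def test_one_absent_breaks_consensus(self):
        calls = calls_from_rows(
            [("h", "g1", "s0", "x", "P"), ("h", "g1", "s1", "x", "P"),
             ("h", "g1", "s2", "x", "A")]
        )
        assert consensus_states(calls, "h", "g1").tissue_states("h") == {"x": False}

    def test_marginal_breaks_consensus(self):
        calls = calls_from_rows(
            [("h", "g1", "s0", "x", "P"), ("h", "g1", "s1", "x", "M"),
             ("h", "g1", "s2", "x", "P")]
        )
        assert consensus_states(calls, "h", "g1").tissue_states("h") == {"x": False}

    def test_unknown_group_rejected(self):
        calls = calls_from_rows([("h", "g1", "s0", "x", "P")])
        with pytest.raises(ExpressionDataError):
            consensus_states(calls, "h", "nope")

    def test_mismatched_gene_universe_rejected(self):
        calls = calls_from_rows(
            [("h", "g1", "s0", "x", "P"), ("h", "g1", "s1", "y", "P")]
        )
        with pytest.raises(ExpressionDataError):
            consensus_states(calls, "h", "g1")

    def test_tsv_roundtrip(self, tmp_path):
        calls = calls_from_rows(
            [("h", "g1", "s0", "x", "P"), ("h", "g1", "s0", "y", "A"),
             ("h", "g1", "s1", "x", "M"), ("h", "g1", "s1", "y", "P")]
        )
        path = tmp_path / "calls.tsv"
        calls.to_tsv(path)
        loaded = ExpressionCallSet.from_tsv(path)
        assert loaded.calls == calls.calls

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_anti_monotone_under_subsetting(self, data):
        """Dropping samples can only move genes absent -> present: a
        unanimity cannot be broken by removal."""
        n = data.draw(st.integers(min_value=2, max_value=6))
        gene_calls = data.draw(
            st.lists(st.sampled_from("PAM"), min_size=n, max_size=n)
        )
        keep_mask = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(any)
        )
        calls = calls_from_rows(
            [("h", "g", f"s{i}", "x", c) for i, c in enumerate(gene_calls)]
        )
        full = consensus_states(calls, "h", "g").tissue_states("h")["x"]
        keep = [f"s{i}" for i, k in enumerate(keep_mask) if k]
        sub = calls.subset("h", "g", keep)
        subset_state = consensus_states(sub, "h", "g").tissue_states("h")["x"]
        assert not (full and not subset_state)


class TestReactionStates:
    def test_or_rule_present(self, starved):
        mt, _ = starved
        calls = toy_expression(mt, "identical")
        states = group_states(mt, calls, "g1")
        rstates = reaction_states(mt, states)
        assert all(rstates.values())

    def test_empty_gpr_and_blood_reactions_present(self, starved):
        mt, _ = starved
        states = GeneStateSet(states={"h": {g: False for g in mt.model.genes}})
        rstates = reaction_states(mt, states)
        assert rstates["HCO3_BUFFER[bl]"] is True     # blood-created
        assert rstates["ATPM[h]"] is True             # empty GPR
        assert rstates["GNG[h]"] is False             # hepatic gene absent

    def test_states_resolved_per_tissue(self, starved):
        """A hepatic reaction follows hepatic gene states even when the
        muscle map says otherwise for the same gene id."""
        mt, _ = starved
        states = GeneStateSet(
            states={"h": {"HLDH1": False}, "m": {"HLDH1": True}}
        )
        rstates = reaction_states(mt, states)
        assert rstates["LDH[h]"] is False
        assert rstates["GLYC[m]"] is True


class TestGimme:
    def test_all_present_keeps_everything(self, starved):
        mt, rmf = starved
        rstates = {rid: True for rid in mt.model.reactions}
        ctx = gimme_extract(mt, rstates, rmf, 0.9)
        assert ctx.removed_reactions == set()
        assert ctx.retained_despite_absent == set()
        assert ctx.penalty == pytest.approx(0.0, abs=1e-9)
        assert set(ctx.model.reactions) == set(mt.model.reactions)

    def test_redundant_absent_path_removed(self, starved):
        """The pyruvate-oxidation route is removed when called absent: the
        LDH + lactate-oxidation route still meets the RMF at full value."""
        mt, rmf = starved
        calls = toy_expression(mt, "drop_redundant")
        rstates = reaction_states(mt, group_states(mt, calls, "g2"))
        assert rstates[f"PYROX[h]"] is False
        ctx = gimme_extract(mt, rstates, rmf, 0.9, label="g2")
        assert ctx.removed_reactions == {"PYROX[h]"}
        assert ctx.retained_despite_absent == set()
        achieved = fba(ctx.model, rmf, "max")
        assert achieved.objective_value >= 0.9 * ctx.parent_optimum - 1e-6

    def test_essential_absent_path_retained(self, starved):
        """Gluconeogenesis is the only route to the RMF: its reaction is
        kept despite the absent call and the penalty equals the flux it
        must carry (0.9 x the parent glucose optimum)."""
        mt, rmf = starved
        calls = toy_expression(mt, "drop_essential")
        rstates = reaction_states(mt, group_states(mt, calls, "g2"))
        assert rstates["GNG[h]"] is False
        ctx = gimme_extract(mt, rstates, rmf, 0.9, label="g2")
        assert ctx.retained_despite_absent == {"GNG[h]"}
        assert "GNG[h]" in ctx.model.reactions
        assert ctx.penalty == pytest.approx(0.9 * ctx.parent_optimum, abs=1e-6)

    def test_rmf_guarantee_for_every_context(self, starved):
        mt, rmf = starved
        for scenario in ("identical", "drop_redundant", "drop_essential"):
            calls = toy_expression(mt, scenario)
            for group in ("g1", "g2"):
                rstates = reaction_states(mt, group_states(mt, calls, group))
                ctx = gimme_extract(mt, rstates, rmf, 0.9, label=group)
                achieved = fba(ctx.model, rmf, "max")
                assert (
                    achieved.objective_value
                    >= ctx.fraction * ctx.parent_optimum - 1e-6
                )

    def test_monotone_in_present_set(self, starved):
        """Enlarging the present set never increases the penalty optimum."""
        mt, rmf = starved
        calls = toy_expression(mt, "drop_essential")
        rstates = reaction_states(mt, group_states(mt, calls, "g2"))
        smaller_present = dict(rstates)
        smaller_present["LDH[h]"] = False  # absent superset
        p_small = gimme_extract(mt, smaller_present, rmf, 0.9).penalty
        p_large = gimme_extract(mt, rstates, rmf, 0.9).penalty
        assert p_large <= p_small + 1e-9

    def test_bad_fraction_rejected(self, starved):
        mt, rmf = starved
        with pytest.raises(ValueError):
            gimme_extract(mt, {}, rmf, 0.0)
        with pytest.raises(ValueError):
            gimme_extract(mt, {}, rmf, 1.5)

    def test_infeasible_rmf_rejected(self, starved):
        mt, _ = starved
        with pytest.raises(InfeasibleScenarioError):
            gimme_extract(mt, {}, {"EX_ala[bl]": 1.0}, 0.9)  # pinned uptake


class TestDifferentialActivity:
    def _contexts(self, starved, scenario):
        mt, rmf = starved
        calls = toy_expression(mt, scenario)
        out = {}
        for group in ("g1", "g2"):
            rstates = reaction_states(mt, group_states(mt, calls, group))
            out[group] = gimme_extract(mt, rstates, rmf, 0.9, label=group)
        return out

    def test_identical_contexts_no_exclusive_sets(self, starved):
        ctxs = self._contexts(starved, "identical")
        report = differential_activity(ctxs["g1"], ctxs["g2"])
        assert report.only_in_a == set()
        assert report.only_in_b == set()

    def test_redundant_drop_shows_in_exclusive_set(self, starved):
        ctxs = self._contexts(starved, "drop_redundant")
        report = differential_activity(ctxs["g1"], ctxs["g2"])
        assert "PYROX[h]" in report.only_in_a
        assert report.only_in_b == set()
        # only the dropped route (and its dedicated NADH respiration,
        # which runs exclusively downstream of it) may differ
        assert report.only_in_a <= {"PYROX[h]", "RESP[h]"}

    def test_essential_drop_keeps_exclusive_sets_empty(self, starved):
        ctxs = self._contexts(starved, "drop_essential")
        report = differential_activity(ctxs["g1"], ctxs["g2"])
        assert report.only_in_a == set()
        assert report.only_in_b == set()

    def test_partition_covers_parent(self, starved):
        ctxs = self._contexts(starved, "drop_redundant")
        report = differential_activity(ctxs["g1"], ctxs["g2"])
        assert report.compared_reactions == len(ctxs["g1"].parent.model.reactions)
        sets = [report.only_in_a, report.only_in_b, report.active_in_both,
                report.inactive_in_both]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert not (a & b)

    def test_blocked_membership_is_not_activity(self, starved):
        """A reaction present in a context's network but FVA-blocked there
        does not land in its exclusive set."""
        mt, rmf = starved
        rstates = {rid: True for rid in mt.model.reactions}
        ctx_a = gimme_extract(mt, rstates, rmf, 0.9, label="A")
        ctx_b = gimme_extract(mt, rstates, rmf, 0.9, label="B")
        report = differential_activity(ctx_a, ctx_b)
        # T_ala[m] is in both networks but cannot carry flux under the
        # starvation bounds (no muscle nitrogen source)
        assert "T_ala[m]" in ctx_b.model.reactions
        assert "T_ala[m]" in report.inactive_in_both

    def test_mismatched_parents_rejected(self, starved, params):
        mt, rmf = starved
        other = toy_multitissue(params, kinds=("liver", "muscle"))
        scen = starvation_scenario(params)
        scen.deactivate_tissues = []  # the two-tissue merge has no fat
        scen.bounds = {
            rid: b for rid, b in scen.bounds.items()
            if rid in other.model.reactions
        }
        other_bounded = wrap_multitissue(apply_scenario(other, scen))
        ctx_a = gimme_extract(
            mt, {r: True for r in mt.model.reactions}, rmf, 0.9
        )
        ctx_b = gimme_extract(
            other_bounded,
            {r: True for r in other_bounded.model.reactions}, rmf, 0.9,
        )
        with pytest.raises(ValueError, match="different parents"):
            differential_activity(ctx_a, ctx_b)

    def test_per_tissue_breakdown_totals(self, starved):
        ctxs = self._contexts(starved, "drop_redundant")
        report = differential_activity(ctxs["g1"], ctxs["g2"])
        table = report.per_tissue
        total = int(
            table[[c for c in table.columns if c != "tissue"]].to_numpy().sum()
        )
        assert total == report.compared_reactions


class TestCallStability:
    def test_unanimous_never_flips(self):
        calls = calls_from_rows(
            [("h", "g", f"s{i}", "x", "P") for i in range(4)]
        )
        report = call_stability(calls, 0.5, n_reps=50, seed=1)
        assert report.table["flip_rate"].eq(0.0).all()
        assert report.overall_stability == 1.0

    def test_single_absent_flip_rate_hypergeometric(self):
        """One A among 4 samples, drop 2: the consensus flips iff the A
        sample is dropped, probability C(3,1)/C(4,2) = 1/2."""
        rows = [("h", "g", f"s{i}", "x", "P" if i else "A") for i in range(4)]
        calls = calls_from_rows(rows)
        report = call_stability(calls, 0.5, n_reps=4000, seed=123)
        rate = report.table.loc[report.table["gene"] == "x", "flip_rate"].item()
        assert rate == pytest.approx(0.5, abs=0.03)

    def test_seeded_reproducibility(self):
        rows = [
            ("h", "g", f"s{i}", gene, "P" if (i + j) % 3 else "A")
            for i in range(5)
            for j, gene in enumerate(["x", "y", "z"])
        ]
        calls = calls_from_rows(rows)
        a = call_stability(calls, 0.4, n_reps=50, seed=7)
        b = call_stability(calls, 0.4, n_reps=50, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.overall_stability == b.overall_stability
        c = call_stability(calls, 0.4, n_reps=50, seed=8)
        assert not a.table.equals(c.table) or a.overall_stability != c.overall_stability

    def test_drop_fraction_validated(self):
        calls = calls_from_rows([("h", "g", "s0", "x", "P"),
                                 ("h", "g", "s1", "x", "P")])
        with pytest.raises(ValueError):
            call_stability(calls, 0.0)
        with pytest.raises(ValueError):
            call_stability(calls, 0.6)

    def test_group_exhaustion_rejected(self):
        calls = calls_from_rows([("h", "g", "s0", "x", "P")])
        with pytest.raises(ExpressionDataError):
            call_stability(calls, 0.5)
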
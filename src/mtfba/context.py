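"""Expression-driven context-specific model extraction and comparison.

Presence/absence calls per tissue and patient group are collapsed to a
consensus gene state (present iff present in every sample), mapped onto
reactions through GPR rules, and used by a GIMME-style LP that minimizes
flux through reactions of absent genes while guaranteeing a required
metabolic functionality (RMF).  Two context models are compared by FVA
reaction activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import optlang
import pandas as pd

from .integrate import BLOOD, MultiTissueModel
from .model_core import MetabolicModel
from .simulate import (
    LPProblem,
    OPTIMAL,
    ZERO_TOL,
    InfeasibleScenarioError,
    fba,
    fva,
)

PRESENT = "P"
ABSENT = "A"
MARGINAL = "M"
CALLS = (PRESENT, ABSENT, MARGINAL)


class ExpressionDataError(ValueError):
    """Raised for malformed or inconsistent expression call data."""


class ExpressionCallSet:
    """P/A/M calls keyed by (tissue, group, sample, gene).

    Within one (tissue, group), all samples must share one gene universe.
    """

    def __init__(self) -> None:
        #: (tissue, group) -> sample -> gene -> call
        self.calls: Dict[tuple[str, str], Dict[str, Dict[str, str]]] = {}

    def add_call(self, tissue: str, group: str, sample: str, gene: str,
                 call: str) -> None:
        if call not in CALLS:
            raise ExpressionDataError(
                f"call must be one of {CALLS}, got {call!r} "
                f"({tissue}/{group}/{sample}/{gene})"
            )
        self.calls.setdefault((tissue, group), {}).setdefault(sample, {})[gene] = call

    def groups(self) -> list[tuple[str, str]]:
        return sorted(self.calls)

    def samples(self, tissue: str, group: str) -> list[str]:
        try:
            return sorted(self.calls[(tissue, group)])
        except KeyError:
            raise ExpressionDataError(
                f"no calls for tissue {tissue!r}, group {group!r}"
            ) from None

    def genes(self, tissue: str, group: str) -> list[str]:
        samples = self.calls[(tissue, group)]
        universes = {frozenset(g) for g in samples.values()}
        if len(universes) > 1:
            raise ExpressionDataError(
                f"samples of ({tissue!r}, {group!r}) disagree on the gene universe"
            )
        return sorted(next(iter(universes))) if universes else []

    def validate(self) -> None:
        for tissue, group in self.groups():
            self.genes(tissue, group)

    # -- I/O ------------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionCallSet":
        required = {"tissue", "group", "sample", "gene_id", "call"}
        missing = required - set(df.columns)
        if missing:
            raise ExpressionDataError(f"missing columns {sorted(missing)}")
        out = cls()
        for row in df.itertuples(index=False):
            out.add_call(
                str(row.tissue), str(row.group), str(row.sample),
                str(row.gene_id), str(row.call),
            )
        out.validate()
        return out

    @classmethod
    def from_tsv(cls, path) -> "ExpressionCallSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tissue, group), samples in sorted(self.calls.items()):
            for sample in sorted(samples):
                for gene in sorted(samples[sample]):
                    rows.append(
                        (tissue, group, sample, gene, samples[sample][gene])
                    )
        return pd.DataFrame(
            rows, columns=["tissue", "group", "sample", "gene_id", "call"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def subset(self, tissue: str, group: str,
               keep_samples: Iterable[str]) -> "ExpressionCallSet":
        """Copy restricted to the given samples of one (tissue, group)."""
        keep = set(keep_samples)
        out = ExpressionCallSet()
        samples = self.calls[(tissue, group)]
        unknown = keep - set(samples)
        if unknown:
            raise ExpressionDataError(f"unknown samples {sorted(unknown)}")
        for sample in keep:
            for gene, call in samples[sample].items():
                out.add_call(tissue, group, sample, gene, call)
        return out


@dataclass
class GeneStateSet:
    """Binary gene states per tissue, derived from calls by consensus."""

    states: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    group: str | None = None

    def tissue_states(self, tissue: str) -> Dict[str, bool]:
        return self.states.get(tissue, {})

    def update(self, other: "GeneStateSet") -> "GeneStateSet":
        for tissue, genes in other.states.items():
            self.states.setdefault(tissue, {}).update(genes)
        return self

    def absent_genes(self, tissue: str) -> set[str]:
        return {g for g, present in self.tissue_states(tissue).items() if not present}


def consensus_states(
    calls: ExpressionCallSet, tissue: str, group: str
) -> GeneStateSet:
    """Gene present iff called P in every sample of the tissue/group.

    Marginal (M) calls break consensus: only unanimous P yields present.
    """
    samples = calls.samples(tissue, group)
    if not samples:
        raise ExpressionDataError(
            f"empty sample set for tissue {tissue!r}, group {group!r}"
        )
    genes = calls.genes(tissue, group)
    data = calls.calls[(tissue, group)]
    states = {
        gene: all(data[sample][gene] == PRESENT for sample in samples)
        for gene in genes
    }
    return GeneStateSet(states={tissue: states}, group=group)


def reaction_states(
    mt: MultiTissueModel, gene_states: GeneStateSet
) -> Dict[str, bool]:
    """Per-reaction presence from GPR rules and tissue-resolved gene states.

    Each reaction is evaluated against the gene states of its tissue of
    origin (via provenance); reactions with empty GPR rules and
    blood-created reactions are present.  Genes missing from a tissue's
    state map count as present.
    """
    out: Dict[str, bool] = {}
    for rid, rxn in mt.model.reactions.items():
        tissue, _ = mt.provenance[rid]
        if tissue == BLOOD or rxn.gpr.is_empty:
            out[rid] = True
        else:
            out[rid] = rxn.gpr.evaluate(gene_states.tissue_states(tissue), default=True)
    return out


@dataclass
class ContextModel:
    """An expression-reduced multi-tissue model.

    ``removed_reactions`` are absent reactions that carried no flux in the
    GIMME optimum and were dropped; ``retained_despite_absent`` are absent
    reactions kept because the RMF guarantee needs them.  The reduced
    model achieves at least ``fraction`` x the parent RMF optimum.
    """

    parent: MultiTissueModel
    model: MetabolicModel
    rmf: Dict[str, float]
    fraction: float
    parent_optimum: float
    rmf_threshold: float
    removed_reactions: set[str]
    retained_despite_absent: set[str]
    penalty: float
    reaction_states: Dict[str, bool]
    label: str = ""

    @property
    def kept_reactions(self) -> set[str]:
        return set(self.model.reactions)

    def validate(self) -> None:
        parent_rxns = set(self.parent.model.reactions)
        if self.removed_reactions & self.kept_reactions:
            raise ValueError("removed and kept reaction sets overlap")
        if self.removed_reactions | self.kept_reactions != parent_rxns:
            raise ValueError("removed + kept reactions do not cover the parent")
        if self.retained_despite_absent - self.kept_reactions:
            raise ValueError("retained_despite_absent reactions missing from model")
        achieved = fba(self.model, self.rmf, "max")
        if not achieved.optimal or (
            achieved.objective_value < self.rmf_threshold - 1e-6
        ):
            raise ValueError(
                f"context model misses its RMF guarantee "
                f"({achieved.objective_value} < {self.rmf_threshold})"
            )


def gimme_extract(
    mt: MultiTissueModel,
    rstates: Mapping[str, bool],
    rmf: Mapping[str, float],
    fraction: float = 0.9,
    tol: float = ZERO_TOL,
    label: str = "",
) -> ContextModel:
    """GIMME: minimize total flux through absent reactions subject to the
    required metabolic functionality staying above ``fraction`` x optimum.

    Absent reactions with zero flux in the minimizing solution are removed;
    absent reactions still carrying flux are retained (needed to meet the
    RMF).  Penalties are binary (1 per unit absolute flux through an
    absent reaction) because upstream calls are binary P/A.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    model = mt.model
    unknown = [r for r in rstates if r not in model.reactions]
    if unknown:
        raise KeyError(f"reaction states reference unknown reaction(s) {unknown}")
    parent_solution = fba(model, dict(rmf), "max")
    if not parent_solution.optimal:
        raise InfeasibleScenarioError(
            f"RMF is {parent_solution.status} in the parent model"
        )
    parent_opt = parent_solution.objective_value
    if parent_opt <= tol:
        raise InfeasibleScenarioError(
            "parent RMF optimum is not positive; GIMME needs a positive target"
        )
    threshold = fraction * parent_opt

    absent = sorted(r for r, present in rstates.items() if not present)
    lp = LPProblem(model)
    lp.add_constraint(dict(rmf), lb=threshold, ub=None, name="rmf_guarantee")
    aux_terms = []
    for rid in absent:
        var = lp.variables[rid]
        aux = optlang.Variable(f"abs_{rid}", lb=0)
        lp.lp.add(aux)
        lp.lp.add(optlang.Constraint(aux - var, lb=0, name=f"abs_pos_{rid}"))
        lp.lp.add(optlang.Constraint(aux + var, lb=0, name=f"abs_neg_{rid}"))
        aux_terms.append(aux)
    if aux_terms:
        lp.lp.objective = optlang.Objective(sum(aux_terms), direction="min")
    else:
        lp.set_objective(dict(rmf), "max")
    status = lp.lp.optimize()
    if status == "undefined":
        status = "infeasible"
    if status != OPTIMAL:
        raise InfeasibleScenarioError(f"GIMME LP is {status}")
    penalty = float(lp.lp.objective.value) if aux_terms else 0.0
    fluxes = {rid: var.primal for rid, var in lp.variables.items()}

    removed = {rid for rid in absent if abs(fluxes[rid]) < tol}
    retained = set(absent) - removed
    reduced = model.copy(f"{model.id}_ctx_{label}" if label else f"{model.id}_ctx")
    for rid in removed:
        reduced.remove_reaction(rid)
    reduced.prune_unused_metabolites()

    ctx = ContextModel(
        parent=mt,
        model=reduced,
        rmf=dict(rmf),
        fraction=fraction,
        parent_optimum=parent_opt,
        rmf_threshold=threshold,
        removed_reactions=removed,
        retained_despite_absent=retained,
        penalty=penalty,
        reaction_states=dict(rstates),
        label=label,
    )
    ctx.validate()
    return ctx


@dataclass
class DifferentialActivityReport:
    """FVA-based reaction activity comparison of two context models."""

    only_in_a: set[str]
    only_in_b: set[str]
    active_in_both: set[str]
    inactive_in_both: set[str]
    label_a: str
    label_b: str
    per_tissue: pd.DataFrame

    @property
    def compared_reactions(self) -> int:
        return (
            len(self.only_in_a)
            + len(self.only_in_b)
            + len(self.active_in_both)
            + len(self.inactive_in_both)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, reactions in (
            (f"only_{self.label_a}", self.only_in_a),
            (f"only_{self.label_b}", self.only_in_b),
            ("both", self.active_in_both),
            ("neither", self.inactive_in_both),
        ):
            for rid in sorted(reactions):
                rows.append((rid, name))
        return pd.DataFrame(rows, columns=["reaction_id", "activity"])


def _active_set(ctx: ContextModel, tol: float) -> set[str]:
    result = fva(
        ctx.model,
        constraints=[(ctx.rmf, ctx.rmf_threshold, None)],
    )
    return {
        rid
        for rid in result.minimum
        if result.maximum[rid] >= tol or result.minimum[rid] <= -tol
    }


def differential_activity(
    ctx_a: ContextModel,
    ctx_b: ContextModel,
    tol: float = ZERO_TOL,
) -> DifferentialActivityReport:
    """Compare which reactions can carry flux in each context model.

    A reaction is active in a context iff its FVA range (under the RMF
    guarantee) strays from zero; reactions removed from a context are
    inactive there by construction.  Activity, not network membership, is
    compared.
    """
    if set(ctx_a.parent.model.reactions) != set(ctx_b.parent.model.reactions):
        raise ValueError("context models derive from different parents")
    active_a = _active_set(ctx_a, tol)
    active_b = _active_set(ctx_b, tol)
    universe = set(ctx_a.parent.model.reactions)
    only_a = active_a - active_b
    only_b = active_b - active_a
    both = active_a & active_b
    neither = universe - active_a - active_b

    provenance = ctx_a.parent.provenance
    rows = []
    tissues = sorted({t for t, _ in provenance.values()})
    for tissue in tissues:
        in_tissue = {r for r, (t, _) in provenance.items() if t == tissue}
        rows.append(
            {
                "tissue": tissue,
                f"only_{ctx_a.label or 'A'}": len(only_a & in_tissue),
                f"only_{ctx_b.label or 'B'}": len(only_b & in_tissue),
                "both": len(both & in_tissue),
                "neither": len(neither & in_tissue),
            }
        )
    return DifferentialActivityReport(
        only_in_a=only_a,
        only_in_b=only_b,
        active_in_both=both,
        inactive_in_both=neither,
        label_a=ctx_a.label or "A",
        label_b=ctx_b.label or "B",
        per_tissue=pd.DataFrame(rows),
    )


@dataclass
class StabilityReport:
    """Per-gene consensus flip rates under random sample dropping."""

    table: pd.DataFrame  # columns: tissue, group, gene, flip_rate
    overall_stability: float
    drop_fraction: float
    n_reps: int
    seed: int


def call_stability(
    calls: ExpressionCallSet,
    drop_fraction: float,
    n_reps: int = 100,
    seed: int = 0,
) -> StabilityReport:
    """Sensitivity of consensus states to dropping samples.

    For each replicate, ceil(drop_fraction x n) samples are removed
    uniformly at random from every (tissue, group); the consensus is
    recomputed and compared with the full-sample consensus.  Since the
    consensus is a unanimity rule, dropping samples can only flip genes
    absent -> present.
    """
    if not 0.0 < drop_fraction <= 0.5:
        raise ValueError(f"drop_fraction must lie in (0, 0.5], got {drop_fraction}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    flip_rates = []
    for tissue, group in calls.groups():
        samples = calls.samples(tissue, group)
        n = len(samples)
        k = math.ceil(drop_fraction * n)
        if n - k < 1:
            raise ExpressionDataError(
                f"dropping {k} of {n} samples exhausts ({tissue!r}, {group!r})"
            )
        baseline = consensus_states(calls, tissue, group).tissue_states(tissue)
        genes = sorted(baseline)
        flips = {gene: 0 for gene in genes}
        for _ in range(n_reps):
            dropped = rng.choice(n, size=k, replace=False)
            keep = [s for i, s in enumerate(samples) if i not in set(dropped)]
            sub = calls.subset(tissue, group, keep)
            states = consensus_states(sub, tissue, group).tissue_states(tissue)
            for gene in genes:
                if states[gene] != baseline[gene]:
                    flips[gene] += 1
        for gene in genes:
            rate = flips[gene] / n_reps
            rows.append((tissue, group, gene, rate))
            flip_rates.append(rate)
    table = pd.DataFrame(rows, columns=["tissue", "group", "gene", "flip_rate"])
    overall = 1.0 - (float(np.mean(flip_rates)) if flip_rates else 0.0)
    return StabilityReport(
        table=table,
        overall_stability=overall,
        drop_fraction=drop_fraction,
        n_reps=n_reps,
        seed=seed,
    )
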
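"""Elemental and charge balance checking.

Exchange, biomass, and buffer-kind reactions are skipped by default:
exchanges are system boundaries and biomass functions drain
pseudo-species, so a net production there is intentional.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .types import (
    MetabolicModel,
    ReactionKind,
    net_formula_and_charge,
)

#: Reaction kinds checked by default.
CHECKED_KINDS = (ReactionKind.INTERNAL, ReactionKind.TRANSPORTER)

#: Buffer reactions are chemistry, not plumbing, so they can be opted in.
STATUS_BALANCED = "balanced"
STATUS_UNBALANCED = "unbalanced"
STATUS_UNCHECKABLE = "uncheckable"
STATUS_SKIPPED = "skipped"


def balance_report(
    model: MetabolicModel,
    kinds: Iterable[ReactionKind] = CHECKED_KINDS,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Per-reaction element/charge imbalance table.

    Returns a DataFrame indexed by reaction id with columns ``status``,
    ``net_elements`` (element -> net production map; empty when balanced),
    ``net_charge`` and ``kind``.  A reaction is balanced iff every element
    net and the charge net are zero.  Reactions whose kind is not in
    ``kinds`` get status ``skipped``; checked reactions with missing
    formulas or charges get ``uncheckable`` (never reported as balanced).
    """
    kinds = tuple(ReactionKind(k) for k in kinds)
    rows = []
    for rxn in model.reactions.values():
        if rxn.kind not in kinds:
            rows.append((rxn.id, STATUS_SKIPPED, {}, float("nan"), rxn.kind.value))
            continue
        net = net_formula_and_charge(model, rxn)
        if net is None:
            rows.append(
                (rxn.id, STATUS_UNCHECKABLE, {}, float("nan"), rxn.kind.value)
            )
            continue
        net_elements, net_charge = net
        net_elements = {e: c for e, c in net_elements.items() if abs(c) > tol}
        balanced = not net_elements and abs(net_charge) <= tol
        rows.append(
            (
                rxn.id,
                STATUS_BALANCED if balanced else STATUS_UNBALANCED,
                net_elements,
                net_charge,
                rxn.kind.value,
            )
        )
    df = pd.DataFrame(
        rows, columns=["reaction_id", "status", "net_elements", "net_charge", "kind"]
    )
    return df.set_index("reaction_id")


def is_balanced(report: pd.DataFrame) -> bool:
    """True iff no checked reaction is unbalanced or uncheckable."""
    return not report["status"].isin([STATUS_UNBALANCED, STATUS_UNCHECKABLE]).any()


def unbalanced_reactions(report: pd.DataFrame) -> list[str]:
    return list(report.index[report["status"] == STATUS_UNBALANCED])
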
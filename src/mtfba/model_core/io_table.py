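"""Tab-delimited model format.

Reaction table columns::

    reaction_id  equation  lower_bound  upper_bound  objective_coefficient
    gpr  subsystem  kind

with equations written as ``2 lac[bl] + 6 atp[h_c] -> glc[bl] + 6 adp[h_c]``
(reversibility is carried by the bounds, not the arrow).  A metabolite
sidecar table (``<model>.mets.tsv``) holds ``id``, ``formula``, ``charge``
and ``name``.  Writing is deterministic and byte-stable under load/save
round trips.
"""

from __future__ import annotations

import re
from pathlib import Path

from .gpr import parse_gpr
from .types import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelConsistencyError,
    Reaction,
    ReactionKind,
    format_number,
)

_REACTION_COLUMNS = [
    "reaction_id",
    "equation",
    "lower_bound",
    "upper_bound",
    "objective_coefficient",
    "gpr",
    "subsystem",
    "kind",
]
_MET_COLUMNS = ["id", "formula", "charge", "name"]

_ARROWS = ("<=>", "<->", "=>", "->")
_TERM = re.compile(r"^(?:(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s+)?(?P<met>\S.*)$")


class TableFormatError(ValueError):
    """Raised when a table-format file cannot be parsed."""


def sidecar_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".mets.tsv")


def _parse_side(side: str, sign: int, equation: str) -> dict[str, float]:
    out: dict[str, float] = {}
    side = side.strip()
    if not side:
        return out
    for term in side.split(" + "):
        term = term.strip()
        if not term:
            raise TableFormatError(f"empty term in equation {equation!r}")
        m = _TERM.match(term)
        if not m:
            raise TableFormatError(f"cannot parse term {term!r} in {equation!r}")
        coef = float(m.group("coef")) if m.group("coef") else 1.0
        met = m.group("met").strip()
        out[met] = out.get(met, 0.0) + sign * coef
    return out


def parse_equation(equation: str) -> dict[str, float]:
    """Parse an equation string into a metabolite -> coefficient map."""
    for arrow in _ARROWS:
        if arrow in equation:
            lhs, rhs = equation.split(arrow, 1)
            break
    else:
        raise TableFormatError(f"no reaction arrow found in {equation!r}")
    stoich = _parse_side(lhs, -1, equation)
    for met, coef in _parse_side(rhs, +1, equation).items():
        stoich[met] = stoich.get(met, 0.0) + coef
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise TableFormatError(f"equation {equation!r} has no net stoichiometry")
    return stoich


def save_table(model: MetabolicModel, path: str | Path) -> None:
    """Write a model as a reaction TSV plus a metabolite sidecar TSV."""
    path = Path(path)
    lines = ["\t".join(_REACTION_COLUMNS)]
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    rxn.equation_string(),
                    format_number(rxn.lower_bound),
                    format_number(rxn.upper_bound),
                    format_number(model.objective.get(rid, 0.0)),
                    rxn.gpr.to_string(),
                    rxn.subsystem,
                    rxn.kind.value,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")

    met_lines = ["\t".join(_MET_COLUMNS)]
    for mid in sorted(model.metabolites):
        met = model.metabolites[mid]
        met_lines.append(
            "\t".join(
                [
                    met.id,
                    met.formula or "",
                    "" if met.charge is None else str(met.charge),
                    met.name,
                ]
            )
        )
    sidecar_path(path).write_text("\n".join(met_lines) + "\n")


def load_table(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Read a model written by :func:`save_table`.

    Metabolites referenced by equations but missing from the sidecar (or
    when no sidecar exists) are created without formula/charge.  Bounds
    absent in the file default to +/-1000.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    model = MetabolicModel(model_id or path.stem)

    side = sidecar_path(path)
    if side.exists():
        header, *rows = side.read_text().splitlines()
        cols = header.split("\t")
        for lineno, row in enumerate(rows, start=2):
            if not row.strip():
                continue
            fields = dict(zip(cols, row.split("\t")))
            try:
                model.add_metabolite(
                    Metabolite(
                        id=fields["id"],
                        formula=fields.get("formula") or None,
                        charge=int(fields["charge"]) if fields.get("charge") else None,
                        name=fields.get("name", ""),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise TableFormatError(f"{side}:{lineno}: {exc}") from exc

    header_line, *rows = path.read_text().splitlines()
    cols = header_line.split("\t")
    if "reaction_id" not in cols or "equation" not in cols:
        raise TableFormatError(
            f"{path}: missing required columns reaction_id/equation"
        )
    objective: dict[str, float] = {}
    for lineno, row in enumerate(rows, start=2):
        if not row.strip():
            continue
        fields = dict(zip(cols, row.split("\t")))
        rid = fields["reaction_id"]
        try:
            stoich = parse_equation(fields["equation"])
        except TableFormatError as exc:
            raise TableFormatError(f"{path}:{lineno} ({rid}): {exc}") from exc
        for met_id in stoich:
            if met_id not in model.metabolites:
                model.add_metabolite(Metabolite(id=met_id))
        lb = float(fields["lower_bound"]) if fields.get("lower_bound") else -DEFAULT_BOUND
        ub = float(fields["upper_bound"]) if fields.get("upper_bound") else DEFAULT_BOUND
        try:
            rxn = Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=parse_gpr(fields.get("gpr", "")),
                subsystem=fields.get("subsystem", ""),
                kind=ReactionKind(fields.get("kind") or "internal"),
            )
        except (ValueError, ModelConsistencyError) as exc:
            raise TableFormatError(f"{path}:{lineno} ({rid}): {exc}") from exc
        model.add_reaction(rxn)
        coef = float(fields.get("objective_coefficient") or 0.0)
        if coef:
            objective[rid] = coef
    model.set_objective(objective)
    model.validate()
    return model
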
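"""Core domain types, GPR evaluation, balance checking, and model I/O."""

from __future__ import annotations

from pathlib import Path

from .balance import (
    balance_report,
    is_balanced,
    unbalanced_reactions,
)
from .gpr import (
    BoolNode,
    GeneLeaf,
    GPRError,
    GPRNode,
    GPRRule,
    evaluate_gpr,
    parse_gpr,
)
from .io_sbml import SBMLFormatError, from_cobra, load_sbml, save_sbml, to_cobra
from .io_table import TableFormatError, load_table, parse_equation, save_table
from .types import (
    DEFAULT_BOUND,
    FormulaError,
    MetabolicModel,
    Metabolite,
    ModelConsistencyError,
    Reaction,
    ReactionKind,
    format_number,
    make_met_id,
    net_formula_and_charge,
    parse_formula,
    split_met_id,
)

FORMATS = ("sbml", "table")


def _guess_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix in (".tsv", ".txt", ".tab"):
        return "table"
    raise ValueError(
        f"cannot guess model format from {path!r}; pass format='sbml' or 'table'"
    )


def load_model(path: str | Path, format: str | None = None) -> MetabolicModel:
    """Load a model from SBML or the tab-delimited format."""
    fmt = format or _guess_format(path)
    if fmt == "sbml":
        return load_sbml(path)
    if fmt == "table":
        return load_table(path)
    raise ValueError(f"unknown model format {fmt!r}; expected one of {FORMATS}")


def save_model(model: MetabolicModel, path: str | Path, format: str | None = None) -> None:
    """Save a model to SBML (Level 3 + fbc) or the tab-delimited format."""
    fmt = format or _guess_format(path)
    if fmt == "sbml":
        save_sbml(model, path)
    elif fmt == "table":
        save_table(model, path)
    else:
        raise ValueError(f"unknown model format {fmt!r}; expected one of {FORMATS}")


__all__ = [
    "DEFAULT_BOUND",
    "FORMATS",
    "BoolNode",
    "FormulaError",
    "GPRError",
    "GPRNode",
    "GPRRule",
    "GeneLeaf",
    "MetabolicModel",
    "Metabolite",
    "ModelConsistencyError",
    "Reaction",
    "ReactionKind",
    "SBMLFormatError",
    "TableFormatError",
    "balance_report",
    "evaluate_gpr",
    "format_number",
    "from_cobra",
    "is_balanced",
    "load_model",
    "load_sbml",
    "load_table",
    "make_met_id",
    "net_formula_and_charge",
    "parse_equation",
    "parse_formula",
    "parse_gpr",
    "save_model",
    "save_sbml",
    "save_table",
    "split_met_id",
    "to_cobra",
    "unbalanced_reactions",
]
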
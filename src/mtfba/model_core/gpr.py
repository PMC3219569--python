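"""Boolean gene-protein-reaction (GPR) rules.

A rule is a boolean expression tree over gene identifiers with AND/OR
internal nodes.  AND encodes enzyme complexes (all subunits required),
OR encodes isozymes (any one suffices).  The empty rule is always
satisfied: reactions without gene annotation (spontaneous reactions,
free diffusion) are treated as present.
"""

from __future__ import annotations

import re
from typing import Iterator, Mapping


class GPRError(ValueError):
    """Raised for malformed GPR expressions."""


class GPRNode:
    """Base class for nodes of a GPR expression tree."""

    def evaluate(self, states: Mapping[str, bool], default: bool = True) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError


class GeneLeaf(GPRNode):
    __slots__ = ("gene",)

    def __init__(self, gene: str):
        if not gene:
            raise GPRError("gene leaf must carry a non-empty identifier")
        self.gene = gene

    def evaluate(self, states: Mapping[str, bool], default: bool = True) -> bool:
        return bool(states.get(self.gene, default))

    def genes(self) -> frozenset[str]:
        return frozenset((self.gene,))

    def to_string(self) -> str:
        return self.gene

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GeneLeaf({self.gene!r})"


class BoolNode(GPRNode):
    __slots__ = ("op", "children")

    def __init__(self, op: str, children: list[GPRNode]):
        if op not in ("and", "or"):
            raise GPRError(f"unknown boolean operator {op!r}")
        if len(children) < 2:
            raise GPRError(f"{op!r} node needs at least two children")
        if not all(isinstance(c, GPRNode) for c in children):
            raise GPRError("boolean node children must be GPR nodes")
        self.op = op
        self.children = list(children)

    def evaluate(self, states: Mapping[str, bool], default: bool = True) -> bool:
        values = (c.evaluate(states, default) for c in self.children)
        return all(values) if self.op == "and" else any(values)

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, BoolNode) and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"BoolNode({self.op!r}, {self.children!r})"


class GPRRule:
    """A (possibly empty) GPR expression.

    ``GPRRule(None)`` is the empty rule; it evaluates to present and
    references no genes.
    """

    __slots__ = ("root",)

    def __init__(self, root: GPRNode | None = None):
        if root is not None and not isinstance(root, GPRNode):
            raise GPRError("GPR root must be a GPRNode or None")
        self.root = root

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def evaluate(self, states: Mapping[str, bool], default: bool = True) -> bool:
        """Evaluate to True (present) or False (absent).

        Genes missing from ``states`` take ``default`` (present by
        default: absence of evidence is not evidence of absence).
        """
        if self.root is None:
            return True
        return self.root.evaluate(states, default)

    def genes(self) -> frozenset[str]:
        return frozenset() if self.root is None else self.root.genes()

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GPRRule):
            return NotImplemented
        return self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"GPRRule({self.to_string()!r})"


_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> Iterator[str]:
    for tok in _TOKEN.findall(text):
        yield tok


def parse_gpr(text: str | None) -> GPRRule:
    """Parse a GPR string such as ``"g1 and (g2 or g3)"``.

    ``and``/``or`` are case-insensitive; ``&&``/``||`` and ``&``/``|``
    are accepted as synonyms (seen in legacy SBML notes).  An empty or
    whitespace-only string yields the empty rule.
    """
    if text is None or not text.strip():
        return GPRRule(None)
    tokens = list(_tokenize(text))
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: str | None, op: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == op or (op == "and" and low in ("&", "&&")) or (
            op == "or" and low in ("|", "||")
        )

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRError(f"unexpected end of GPR expression: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GPRError(f"misplaced token {tok!r} in GPR: {text!r}")
        return GeneLeaf(take())

    def parse_and() -> GPRNode:
        children = [parse_atom()]
        while is_op(peek(), "and"):
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else BoolNode("and", children)

    def parse_or() -> GPRNode:
        children = [parse_and()]
        while is_op(peek(), "or"):
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else BoolNode("or", children)

    root = parse_or()
    if pos != len(tokens):
        raise GPRError(f"trailing tokens in GPR expression: {text!r}")
    return GPRRule(root)


def evaluate_gpr(rule: GPRRule, gene_states: Mapping[str, bool],
                 default: bool = True) -> bool:
    """Functional form of :meth:`GPRRule.evaluate`."""
    if not isinstance(rule, GPRRule):
        raise GPRError("evaluate_gpr expects a GPRRule")
    return rule.evaluate(gene_states, default)
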
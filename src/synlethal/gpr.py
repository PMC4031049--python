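"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule is a boolean formula over gene identifiers in which ``and``
encodes an enzyme complex (every subunit gene is required) and ``or``
encodes isoenzymes (any alternative suffices). Rules are parsed into an
explicit tree so they can be evaluated under gene knockouts and so that
"gene units" -- maximal AND-subtrees, i.e. one complex or one standalone
gene -- can be enumerated for counting.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GeneRef:
    gene: str

    def evaluate(self, knocked_out: frozenset[str] | set[str]) -> bool:
        return self.gene not in knocked_out

    @property
    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class BoolOp:
    op: str  # "and" | "or"
    children: tuple["GeneRef | BoolOp", ...]

    def evaluate(self, knocked_out: frozenset[str] | set[str]) -> bool:
        if self.op == "and":
            return all(c.evaluate(knocked_out) for c in self.children)
        return any(c.evaluate(knocked_out) for c in self.children)

    @property
    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.genes
        return out

    def to_string(self) -> str:
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, BoolOp) and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


GPRNode = GeneRef | BoolOp

_TOKEN_RE = re.compile(r"\(|\)|\b[Aa][Nn][Dd]\b|\b[Oo][Rr]\b|[^\s()]+")


@dataclass(frozen=True)
class GeneAssociation:
    """Parsed GPR rule; ``root is None`` means the reaction has no known genes."""

    root: GPRNode | None = None
    raw: str = ""

    @property
    def is_empty(self) -> bool:
        return self.root is None

    @property
    def genes(self) -> frozenset[str]:
        return frozenset() if self.root is None else self.root.genes

    def evaluate(self, knocked_out: set[str] | frozenset[str]) -> bool:
        """Whether the reaction retains catalysis when ``knocked_out`` genes are lost.

        An empty association always evaluates True (no genetic dependency).
        """
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(knocked_out))

    def gene_units(self) -> list[frozenset[str]]:
        """Maximal AND-subtrees as gene sets: one unit per complex or lone gene.

        OR-alternatives are separate units; nested ANDs below an OR are
        flattened into the unit of genes they require jointly.
        """
        if self.root is None:
            return []
        units: list[frozenset[str]] = []

        def walk(node: GPRNode) -> None:
            if isinstance(node, BoolOp) and node.op == "or":
                for c in node.children:
                    walk(c)
            else:
                units.append(node.genes)

        walk(self.root)
        return units

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str | None) -> GeneAssociation:
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a GeneAssociation.

    ``and`` binds tighter than ``or``; both are case-insensitive. Empty or
    whitespace-only input yields an empty association.
    """
    if text is None or not text.strip():
        return GeneAssociation(None, "")
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return BoolOp("or", tuple(terms))

    def parse_and() -> GPRNode:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        if len(terms) == 1:
            return terms[0]
        return BoolOp("and", tuple(terms))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR expression: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parenthesis in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR: {text!r}")
        return GeneRef(take())

    root = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR: {text!r}")
    return GeneAssociation(root, text.strip())
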
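"""Constraint-based model documents and gene–protein–reaction (GPR) logic.

The in-memory model is a plain stoichiometric document: metabolites,
reactions with bounds and a GPR boolean string, and a biomass objective.
GPR strings use the conventional infix syntax, e.g.::

    gA and (gB or gC)

``and`` encodes complex subunits (all genes required), ``or`` isozymes
(any one suffices).  An empty GPR means the reaction is constitutively
active (spontaneous or gene-association unknown).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterator, Union

from .errors import ParseError, ValidationError

# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

#: GPR tree: a gene id (leaf) or ("and"|"or", tuple of children).
GprNode = Union[str, tuple]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str | None) -> GprNode | None:
    """Parse a GPR string into a boolean tree.

    Returns ``None`` for empty/whitespace-only input (constitutively
    active).  Operators ``and``/``or`` are case-insensitive; parentheses
    group as usual; ``and`` binds tighter than ``or``.
    """
    if text is None or not text.strip():
        return None
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", tuple(terms))

    def parse_and() -> GprNode:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else ("and", tuple(factors))

    def parse_atom() -> GprNode:
        tok = peek()
        if tok is None:
            raise ParseError(f"GPR ended unexpectedly: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ParseError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return take()

    node = parse_or()
    if pos != len(tokens):
        raise ParseError(f"trailing tokens in GPR: {text!r}")
    return node


def gpr_genes(node: GprNode | None) -> frozenset[str]:
    """Set of gene ids appearing in a GPR tree."""
    if node is None:
        return frozenset()
    if isinstance(node, str):
        return frozenset((node,))
    out: set[str] = set()
    for child in node[1]:
        out |= gpr_genes(child)
    return frozenset(out)


def evaluate_gpr(node: GprNode | None, deleted: frozenset[str] | set[str]) -> bool:
    """Evaluate a GPR tree under a set of deleted genes.

    A leaf is active iff its gene is not deleted; AND requires all
    children active, OR any; an empty expression is always active.
    """
    if node is None:
        return True
    if isinstance(node, str):
        return node not in deleted
    op, children = node
    if op == "and":
        return all(evaluate_gpr(c, deleted) for c in children)
    if op == "or":
        return any(evaluate_gpr(c, deleted) for c in children)
    raise ValidationError(f"unknown GPR operator {op!r}")


def gpr_to_string(node: GprNode | None) -> str:
    if node is None:
        return ""
    if isinstance(node, str):
        return node
    op, children = node
    sep = f" {op} "
    parts = []
    for c in children:
        s = gpr_to_string(c)
        if isinstance(c, tuple):
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


# ---------------------------------------------------------------------------
# Model document
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry map, flux bounds, GPR string."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        # parse eagerly so malformed GPRs fail at construction
        parse_gpr(self.gpr)

    @property
    def gpr_tree(self) -> GprNode | None:
        return parse_gpr(self.gpr)

    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr_tree)


@dataclass
class ModelDocument:
    """A small constraint-based metabolic model.

    ``metabolites`` maps metabolite id to compartment.  Steady state is
    imposed on every metabolite; exchange with the environment is written
    as reactions with one-sided stoichiometry (e.g. ``{} -> C``).
    """

    id: str
    metabolites: dict[str, str]
    reactions: list[Reaction]
    objective_id: str

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reactions:
            if r.id in seen:
                raise ValidationError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            unknown = set(r.stoichiometry) - set(self.metabolites)
            if unknown:
                raise ValidationError(
                    f"reaction {r.id}: unknown metabolites {sorted(unknown)}"
                )
        if self.objective_id not in seen:
            raise ValidationError(f"objective reaction {self.objective_id!r} not found")
        self._rindex = {r.id: i for i, r in enumerate(self.reactions)}

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self._rindex[rid]]
        except KeyError:
            raise ValidationError(f"unknown reaction id {rid!r}") from None

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes()
        return frozenset(out)

    def with_bounds(self, rid: str, lb: float, ub: float) -> "ModelDocument":
        """Copy of the model with one reaction's bounds replaced."""
        i = self._rindex.get(rid)
        if i is None:
            raise ValidationError(f"unknown reaction id {rid!r}")
        reactions = list(self.reactions)
        reactions[i] = replace(reactions[i], lower_bound=lb, upper_bound=ub)
        return ModelDocument(self.id, dict(self.metabolites), reactions, self.objective_id)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)
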
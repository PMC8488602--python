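"""Gene-protein-reaction (GPR) rule compilation and evaluation.

Boolean gene rules (``geneA and (geneB or geneC)``) are parsed into
expression trees whose internal nodes evaluate as MIN (for AND) and MAX
(for OR) over gene expression values. AND binds tighter than OR, so the
MINs are always evaluated before the MAXs; explicit parentheses in the
source rule are honored. A reaction without a rule carries the constant
expression 1, leaving its bounds untouched by expression mapping.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import MetabolicModel

__all__ = [
    "GprCompileError",
    "ReactionExpressionMap",
    "truncate_gene_ids",
    "genes_in_rule",
    "parse_rule",
    "compile_reaction_expressions",
    "map_profile_to_model",
    "evaluate_reaction_expression",
]

logger = logging.getLogger(__name__)


class GprCompileError(ValueError):
    """Raised for malformed gene rules (unbalanced parens, stray tokens)."""


# --- expression tree -------------------------------------------------------


class Expr:
    def evaluate(self, x: Sequence[float]) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def genes(self) -> list[str]:
        return []


@dataclass(frozen=True)
class One(Expr):
    """Constant expression for rule-less reactions."""

    def evaluate(self, x):
        return 1.0


@dataclass(frozen=True)
class Gene(Expr):
    gene_id: str
    index: int = -1

    def evaluate(self, x):
        if self.index < 0:
            raise ValueError(f"gene {self.gene_id!r} has no position in the model")
        return float(x[self.index])

    def genes(self):
        return [self.gene_id]


@dataclass(frozen=True)
class Min(Expr):
    children: tuple[Expr, ...]

    def evaluate(self, x):
        return min(c.evaluate(x) for c in self.children)

    def genes(self):
        return [g for c in self.children for g in c.genes()]


@dataclass(frozen=True)
class Max(Expr):
    children: tuple[Expr, ...]

    def evaluate(self, x):
        return max(c.evaluate(x) for c in self.children)

    def genes(self):
        return [g for c in self.children for g in c.genes()]


# --- tokenizer / parser ----------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")
_TRAILING_TRANSCRIPT = re.compile(r"\.\d$")


def truncate_gene_ids(ids: Iterable[str]) -> list[str]:
    """Strip exactly one terminal ``.<digit>`` transcript suffix.

    Model genes are often annotated as transcripts (``locus.1``) while
    expression tables carry bare locus tags; matching requires removing
    the suffix. Multi-digit suffixes (``g.12``) are outside the pattern
    and left intact.
    """
    return [_TRAILING_TRANSCRIPT.sub("", gid) for gid in ids]


def _tokenize(rule: str) -> list[str]:
    return _TOKEN.findall(rule)


class _Parser:
    """Recursive-descent parser: rule := term ('or' term)*;
    term := factor ('and' factor)*; factor := gene | '(' rule ')'."""

    def __init__(self, tokens: list[str], gene_index: Mapping[str, int] | None):
        self.tokens = tokens
        self.pos = 0
        self.gene_index = gene_index

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GprCompileError("unexpected end of rule")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.rule()
        if self.peek() is not None:
            raise GprCompileError(f"unexpected token {self.peek()!r}")
        return expr

    def rule(self) -> Expr:
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Max(tuple(terms))

    def term(self) -> Expr:
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else Min(tuple(factors))

    def factor(self) -> Expr:
        tok = self.next()
        if tok == "(":
            inner = self.rule()
            if self.next() != ")":
                raise GprCompileError("unbalanced parentheses")
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprCompileError(f"unexpected token {tok!r}")
        index = -1
        if self.gene_index is not None:
            if tok not in self.gene_index:
                raise GprCompileError(f"unknown gene {tok!r}")
            index = self.gene_index[tok]
        return Gene(tok, index)


def parse_rule(rule: str, gene_index: Mapping[str, int] | None = None) -> Expr:
    """Parse a single boolean gene rule into a MIN/MAX expression tree."""
    tokens = _tokenize(rule)
    if not tokens:
        return One()
    return _Parser(tokens, gene_index).parse()


def genes_in_rule(rule: str) -> list[str]:
    """Gene identifiers appearing in a rule, in order of first appearance."""
    expr = parse_rule(rule)
    seen: dict[str, None] = {}
    for g in expr.genes():
        seen.setdefault(g)
    return list(seen)


# --- compiled map ----------------------------------------------------------


@dataclass
class ReactionExpressionMap:
    """Per-reaction compiled MIN/MAX expressions plus gene bookkeeping.

    ``gene_positions`` lists, for each reaction, the model gene indices
    appearing in its rule. ``genes_by_length`` orders gene identifiers
    by decreasing length; it is kept as a compatibility field for
    string-substitution workflows and is not used by the tree evaluator.
    """

    expressions: list[Expr]
    gene_positions: list[list[int]]
    genes_by_length: list[int]


def compile_reaction_expressions(model: MetabolicModel) -> ReactionExpressionMap:
    gene_index = {g: i for i, g in enumerate(model.genes)}
    expressions: list[Expr] = []
    gene_positions: list[list[int]] = []
    for rid, rule in zip(model.rxns, model.gr_rules):
        try:
            expr = parse_rule(rule, gene_index)
        except GprCompileError as exc:
            raise GprCompileError(f"reaction {rid!r}: {exc}") from exc
        expressions.append(expr)
        seen: dict[int, None] = {}
        for g in expr.genes():
            seen.setdefault(gene_index[g])
        gene_positions.append(list(seen))
    genes_by_length = sorted(
        range(model.n_genes), key=lambda i: len(model.genes[i]), reverse=True
    )
    return ReactionExpressionMap(expressions, gene_positions, genes_by_length)


def map_profile_to_model(
    model: MetabolicModel, profile: Mapping[str, float]
) -> np.ndarray:
    """Build the gene expression vector x for one condition.

    x is initialized to all ones (the neutral fold change); each model
    gene whose truncated identifier matches a profile entry takes the
    profile value. Unmatched model genes stay at 1; profile genes absent
    from the model are ignored (logged at debug level). The vector is
    rebuilt from scratch per condition so values never leak between
    conditions.
    """
    try:
        items = list(profile.items())
    except AttributeError:
        raise TypeError("profile must be a mapping of gene id -> fold change")
    keys = [k for k, _ in items]
    if len(keys) != len(set(keys)):
        raise ValueError("duplicate gene ids in expression profile")
    lookup = dict(items)
    x = np.ones(model.n_genes, dtype=float)
    truncated = truncate_gene_ids(model.genes)
    n_unused = 0
    matched = set()
    for i, tid in enumerate(truncated):
        if tid in lookup:
            x[i] = float(lookup[tid])
            matched.add(tid)
    n_unused = len(set(lookup) - matched)
    if n_unused:
        logger.debug("%d profile genes have no model position", n_unused)
    return x


def evaluate_reaction_expression(expr: Expr, x: Sequence[float]) -> float:
    """Evaluate a compiled expression: MIN at AND nodes, MAX at OR nodes."""
    return expr.evaluate(x)
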
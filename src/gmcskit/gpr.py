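"""Gene-protein rule (GPR) parsing and reaction-level genetic cut sets.

A GPR is a monotone boolean expression over gene identifiers stating which
gene combinations allow flux through a reaction.  Knocking out a gene set
``G`` blocks the reaction exactly when the rule evaluates to false with the
genes of ``G`` set to false.  The inclusion-minimal blocking sets are the
reaction's genetic minimal cut sets (gMCSs); for a rule in conjunctive
normal form they are the minimal clause gene sets, and a rule in
disjunctive normal form is converted by taking the minimal hitting sets
(transversals) of its conjunctive terms.
"""

from __future__ import annotations

import re
import sys
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Optional

__all__ = [
    "GPRError",
    "GPRParseError",
    "GPRComplexityError",
    "GPRExpr",
    "GeneSetFamily",
    "parse_gpr",
    "to_dnf",
    "dnf_to_cnf_factors",
    "reaction_gmcs",
    "reduce_family",
    "evaluate_gpr",
    "is_dnf",
    "is_cnf",
]

#: Guard against combinatorial blow-up while normalizing rules.
DEFAULT_TERM_LIMIT = 10**6

# Below this member size, minimality checks enumerate all proper subsets
# and probe a hash set; above it they fall back to pairwise scans.
_SUBSET_ENUM_MAX = 8


class GPRError(ValueError):
    """Base error for malformed or intractable gene-protein rules."""


class GPRParseError(GPRError):
    """Syntax error in a GPR string; ``position`` is the 0-based offset."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class GPRComplexityError(GPRError):
    """Rule too complex: normalization exceeded the configured term limit."""


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRExpr:
    """Node of a parsed gene-protein rule.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"empty"``.
    Conjunction/disjunction nodes always carry at least two children after
    normalization; literals carry none and hold the gene identifier.
    """

    kind: str
    children: tuple["GPRExpr", ...] = ()
    gene: Optional[str] = None

    # -- constructors -------------------------------------------------------

    @staticmethod
    def empty() -> "GPRExpr":
        return GPRExpr("empty")

    @staticmethod
    def lit(gene: str) -> "GPRExpr":
        return GPRExpr("gene", gene=sys.intern(gene))

    @staticmethod
    def conj(children: Iterable["GPRExpr"]) -> "GPRExpr":
        return _combine("and", children)

    @staticmethod
    def disj(children: Iterable["GPRExpr"]) -> "GPRExpr":
        return _combine("or", children)

    # -- queries ------------------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"

    def genes(self) -> frozenset[str]:
        """All gene identifiers mentioned in the rule."""
        if self.kind == "gene":
            return frozenset((self.gene,))
        out: set[str] = set()
        for child in self.children:
            out.update(child.genes())
        return frozenset(out)

    def evaluate(self, knocked: Iterable[str]) -> bool:
        knocked = frozenset(knocked)
        return _evaluate(self, knocked)

    def to_string(self) -> str:
        """Serialize with ``and`` binding tighter than ``or``."""
        if self.kind == "empty":
            return ""
        if self.kind == "gene":
            return self.gene
        if self.kind == "and":
            parts = [
                f"({c.to_string()})" if c.kind == "or" else c.to_string()
                for c in self.children
            ]
            return " and ".join(parts)
        return " or ".join(c.to_string() for c in self.children)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.to_string()


def _combine(kind: str, children: Iterable[GPRExpr]) -> GPRExpr:
    """Flatten nested nodes of the same kind, dedupe, collapse singletons."""
    flat: list[GPRExpr] = []
    seen: set[GPRExpr] = set()
    for child in children:
        parts = child.children if child.kind == kind else (child,)
        for part in parts:
            if part.kind == "empty":
                raise GPRError("empty sub-expression inside a compound rule")
            if part not in seen:
                seen.add(part)
                flat.append(part)
    if not flat:
        raise GPRError(f"'{kind}' node requires at least one operand")
    if len(flat) == 1:
        return flat[0]
    return GPRExpr(kind, tuple(flat))


def _evaluate(expr: GPRExpr, knocked: frozenset[str]) -> bool:
    if expr.kind == "empty":
        return True
    if expr.kind == "gene":
        return expr.gene not in knocked
    if expr.kind == "and":
        return all(_evaluate(c, knocked) for c in expr.children)
    return any(_evaluate(c, knocked) for c in expr.children)


def evaluate_gpr(expr: GPRExpr, knocked: Iterable[str]) -> bool:
    """Truth value of the rule with genes in ``knocked`` false, rest true.

    The empty rule is vacuously true: a reaction without genetic support is
    unaffected by any knockout.
    """
    return expr.evaluate(knocked)


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(\(|\)|&&?|\|\|?|[^\s()&|]+)")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:  # only trailing whitespace left
            break
        value = match.group(1)
        start = match.start(1)
        if value == "(":
            tokens.append(("LPAREN", value, start))
        elif value == ")":
            tokens.append(("RPAREN", value, start))
        elif value in ("&", "&&") or value.lower() == "and":
            tokens.append(("AND", value, start))
        elif value in ("|", "||") or value.lower() == "or":
            tokens.append(("OR", value, start))
        else:
            tokens.append(("GENE", value, start))
        pos = match.end()
    return tokens


class _Parser:
    """Recursive descent over the token stream; ``and`` binds tighter."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    def peek(self) -> Optional[tuple[str, str, int]]:
        if self.index < len(self.tokens):
            return self.tokens[self.index]
        return None

    def advance(self) -> tuple[str, str, int]:
        token = self.tokens[self.index]
        self.index += 1
        return token

    def parse(self) -> GPRExpr:
        expr = self.parse_or()
        if self.index < len(self.tokens):
            kind, value, pos = self.tokens[self.index]
            raise GPRParseError(f"unexpected '{value}'", pos)
        return expr

    def parse_or(self) -> GPRExpr:
        parts = [self.parse_and()]
        while (token := self.peek()) is not None and token[0] == "OR":
            self.advance()
            parts.append(self.parse_and())
        return GPRExpr.disj(parts)

    def parse_and(self) -> GPRExpr:
        parts = [self.parse_atom()]
        while (token := self.peek()) is not None and token[0] == "AND":
            self.advance()
            parts.append(self.parse_atom())
        return GPRExpr.conj(parts)

    def parse_atom(self) -> GPRExpr:
        token = self.peek()
        if token is None:
            raise GPRParseError("dangling operator or empty operand", len(self.text))
        kind, value, pos = token
        if kind == "GENE":
            self.advance()
            return GPRExpr.lit(value)
        if kind == "LPAREN":
            self.advance()
            inner = self.parse_or()
            closing = self.peek()
            if closing is None or closing[0] != "RPAREN":
                raise GPRParseError("unbalanced parenthesis", pos)
            self.advance()
            return inner
        raise GPRParseError(f"unexpected '{value}'", pos)


def parse_gpr(text: str) -> GPRExpr:
    """Parse a GPR rule string into an expression tree.

    Accepts gene identifiers joined by ``and``/``or`` (case-insensitive,
    ``&``/``|`` synonyms) with parentheses; ``and`` binds tighter than
    ``or``.  An empty or all-whitespace string yields the empty rule.
    Raises :class:`GPRParseError` naming the offending position otherwise.
    """
    if text is None or not text.strip():
        return GPRExpr.empty()
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# Reduction of set collections
# ---------------------------------------------------------------------------

def _proper_subsets(s: frozenset) -> Iterator[frozenset]:
    items = sorted(s)
    for size in range(len(items)):
        for combo in combinations(items, size):
            yield frozenset(combo)


def _reduce_sets(sets: Iterable[frozenset]) -> set[frozenset]:
    """Inclusion-minimal elements of ``sets``, deduplicated."""
    unique = set(sets)
    kept: set[frozenset] = set()
    for s in sorted(unique, key=len):
        if len(s) <= _SUBSET_ENUM_MAX:
            redundant = any(sub in kept for sub in _proper_subsets(s))
        else:
            redundant = any(t < s for t in kept)
        if not redundant:
            kept.add(s)
    return kept


class GeneSetFamily:
    """A reduced collection of gene sets: no member contains another.

    Members are stored in canonical order (each set as its sorted gene
    tuple, sets ordered lexicographically) so iteration and serialization
    are deterministic.  An optional ``cardinality_cap`` k restricts the
    family to members of size <= k; the cap is applied after reduction, so
    a capped family is exactly the <=k slice of the uncapped one.
    """

    __slots__ = ("_members", "_member_set", "cardinality_cap")

    def __init__(self, members: Iterable[Iterable[str]] = (),
                 cardinality_cap: Optional[int] = None):
        if cardinality_cap is not None and cardinality_cap < 1:
            raise ValueError("cardinality_cap must be >= 1")
        reduced = _reduce_sets(frozenset(m) for m in members)
        if cardinality_cap is not None:
            reduced = {s for s in reduced if len(s) <= cardinality_cap}
        self._finalize(reduced, cardinality_cap)

    def _finalize(self, reduced: set[frozenset], cap: Optional[int]) -> None:
        self._members = tuple(sorted(reduced, key=lambda s: tuple(sorted(s))))
        self._member_set = frozenset(reduced)
        self.cardinality_cap = cap

    @classmethod
    def _from_reduced(cls, reduced: Iterable[frozenset],
                      cardinality_cap: Optional[int] = None) -> "GeneSetFamily":
        """Fast path for collections already known to be reduced and capped."""
        family = cls.__new__(cls)
        family._finalize(set(reduced), cardinality_cap)
        return family

    # -- container protocol -------------------------------------------------

    @property
    def members(self) -> tuple[frozenset, ...]:
        return self._members

    def __iter__(self) -> Iterator[frozenset]:
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __bool__(self) -> bool:
        return bool(self._members)

    def __contains__(self, item: Iterable[str]) -> bool:
        return frozenset(item) in self._member_set

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GeneSetFamily):
            return self._member_set == other._member_set
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._member_set)

    def __repr__(self) -> str:
        inner = ", ".join("{" + ",".join(sorted(s)) + "}" for s in self._members)
        return f"GeneSetFamily([{inner}])"

    # -- queries ------------------------------------------------------------

    def min_size(self) -> Optional[int]:
        """Size of the smallest member, or None for the empty family."""
        if not self._members:
            return None
        return min(len(s) for s in self._members)

    def contains_subset_of(self, geneset: Iterable[str]) -> bool:
        """True iff some member is a subset of ``geneset`` (equality counts)."""
        G = frozenset(geneset)
        if len(G) <= _SUBSET_ENUM_MAX:
            items = sorted(G)
            for size in range(len(items) + 1):
                for combo in combinations(items, size):
                    if frozenset(combo) in self._member_set:
                        return True
            return False
        return any(member <= G for member in self._members)

    def restrict(self, cardinality_cap: int) -> "GeneSetFamily":
        """The <=cap slice of this family."""
        return GeneSetFamily._from_reduced(
            (s for s in self._members if len(s) <= cardinality_cap),
            cardinality_cap,
        )

    @classmethod
    def merge(cls, families: Iterable["GeneSetFamily"],
              cardinality_cap: Optional[int] = None) -> "GeneSetFamily":
        """Reduced union of several families."""
        members: list[frozenset] = []
        for family in families:
            members.extend(family.members)
        return cls(members, cardinality_cap=cardinality_cap)

    # -- debug serialization (one set per line, genes comma-separated) -------

    def to_lines(self) -> list[str]:
        return [",".join(sorted(s)) for s in self._members]

    @classmethod
    def from_lines(cls, lines: Iterable[str]) -> "GeneSetFamily":
        members = [
            frozenset(part for part in line.strip().split(",") if part)
            for line in lines
            if line.strip()
        ]
        return cls(members)


def reduce_family(members: Iterable[Iterable[str]]) -> GeneSetFamily:
    """Reduction of a collection of gene sets: keep the inclusion-minimal
    ones, deduplicated, in canonical order.  Idempotent."""
    return GeneSetFamily(members)


# ---------------------------------------------------------------------------
# Normal forms
# ---------------------------------------------------------------------------

def _is_flat(expr: GPRExpr, op: str) -> bool:
    if expr.kind == "gene":
        return True
    return expr.kind == op and all(c.kind == "gene" for c in expr.children)


def is_dnf(expr: GPRExpr) -> bool:
    """True for a literal, a flat conjunction, or a disjunction of those."""
    if expr.kind == "empty":
        return False
    if _is_flat(expr, "and"):
        return True
    return expr.kind == "or" and all(_is_flat(c, "and") for c in expr.children)


def is_cnf(expr: GPRExpr) -> bool:
    """True for a literal, a flat disjunction, or a conjunction of those."""
    if expr.kind == "empty":
        return False
    if _is_flat(expr, "or"):
        return True
    return expr.kind == "and" and all(_is_flat(c, "or") for c in expr.children)


def _flat_gene_sets(expr: GPRExpr, op: str) -> list[frozenset]:
    """Gene sets of the top-level terms of a DNF (op='and') or clauses of a
    CNF (op='or')."""
    if expr.kind == "gene":
        return [frozenset((expr.gene,))]
    if _is_flat(expr, op):
        return [expr.genes()]
    return [child.genes() for child in expr.children]


def to_dnf(expr: GPRExpr, term_limit: int = DEFAULT_TERM_LIMIT) -> list[frozenset]:
    """DNF summands of the rule as gene sets, absorbed and canonically sorted.

    Distributes conjunctions over disjunctions recursively; raises
    :class:`GPRComplexityError` once the intermediate term count exceeds
    ``term_limit`` rather than truncating silently.
    """
    if expr.is_empty:
        raise GPRError("empty rule has no DNF terms")
    terms = _reduce_sets(_dnf_terms(expr, term_limit))
    return sorted(terms, key=lambda s: tuple(sorted(s)))


def _dnf_terms(expr: GPRExpr, term_limit: int) -> set[frozenset]:
    if expr.kind == "gene":
        return {frozenset((expr.gene,))}
    if expr.kind == "or":
        out: set[frozenset] = set()
        for child in expr.children:
            out.update(_dnf_terms(child, term_limit))
            if len(out) > term_limit:
                raise GPRComplexityError(
                    f"rule too complex: more than {term_limit} DNF terms")
        return _reduce_sets(out)
    # conjunction: cross product of the children's term sets
    acc: set[frozenset] = {frozenset()}
    for child in expr.children:
        child_terms = _dnf_terms(child, term_limit)
        if len(acc) * len(child_terms) > term_limit:
            raise GPRComplexityError(
                f"rule too complex: more than {term_limit} DNF terms")
        acc = _reduce_sets({a | b for a in acc for b in child_terms})
    return acc


def dnf_to_cnf_factors(terms: Iterable[Iterable[str]],
                       cardinality_cap: Optional[int] = None,
                       work_limit: int = DEFAULT_TERM_LIMIT) -> GeneSetFamily:
    """CNF factors of a DNF rule: the minimal hitting sets of its term sets.

    Incremental transversal computation (Berge): fold the terms in one at a
    time, extending every partial hitting set that misses the new term by
    each of its genes, then reducing.  With ``cardinality_cap`` k, partial
    sets larger than k are pruned immediately; because every minimal
    transversal of size <= k survives that pruning, the result is exactly
    the <=k slice of the uncapped factor family.
    """
    term_sets = [frozenset(t) for t in terms]
    if not term_sets:
        raise GPRError("cannot convert an empty term list")
    if any(not t for t in term_sets):
        raise GPRError("DNF terms must be nonempty gene sets")
    transversals: set[frozenset] = {frozenset()}
    for term in term_sets:
        grown: set[frozenset] = set()
        for partial in transversals:
            if partial & term:
                grown.add(partial)
            else:
                for gene in term:
                    candidate = partial | {gene}
                    if cardinality_cap is None or len(candidate) <= cardinality_cap:
                        grown.add(candidate)
        if len(grown) > work_limit:
            raise GPRComplexityError(
                f"rule too complex: more than {work_limit} working hitting sets")
        transversals = _reduce_sets(grown)
    return GeneSetFamily._from_reduced(transversals, cardinality_cap)


def reaction_gmcs(expr: GPRExpr, k: Optional[int] = None,
                  term_limit: int = DEFAULT_TERM_LIMIT) -> GeneSetFamily:
    """Genetic minimal cut sets of a single reaction's rule.

    CNF-shaped rules yield the reduced clause gene sets directly; DNF-shaped
    (or arbitrary) rules are converted via :func:`dnf_to_cnf_factors`.  With
    ``k`` set, members larger than k are dropped (the capped family is the
    <=k slice of the uncapped one).  The empty rule yields the empty family:
    the reaction cannot be blocked genetically.
    """
    if expr.is_empty:
        return GeneSetFamily(cardinality_cap=k)
    if is_cnf(expr):
        return GeneSetFamily(_flat_gene_sets(expr, "or"), cardinality_cap=k)
    if is_dnf(expr):
        terms = _reduce_sets(_flat_gene_sets(expr, "and"))
    else:
        terms = set(to_dnf(expr, term_limit))
    return dnf_to_cnf_factors(terms, cardinality_cap=k, work_limit=term_limit)
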
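"""Unit and property tests for GPR parsing and reaction-level cut sets."""

from __future__ import annotations

from itertools import combinations, product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmcskit.gpr import (
    GeneSetFamily,
    GPRComplexityError,
    GPRError,
    GPRExpr,
    GPRParseError,
    dnf_to_cnf_factors,
    evaluate_gpr,
    is_cnf,
    is_dnf,
    parse_gpr,
    reaction_gmcs,
    reduce_family,
    to_dnf,
)


def fam(*sets):
    return {frozenset(s) for s in sets}


# ---------------------------------------------------------------------------
# parse_gpr
# ---------------------------------------------------------------------------

class TestParse:
    def test_r7_rule(self):
        expr = parse_gpr("g0 and (g5 or g6 or g7)")
        assert expr.kind == "and"
        kinds = sorted(c.kind for c in expr.children)
        assert kinds == ["gene", "or"]
        assert expr.genes() == frozenset({"g0", "g5", "g6", "g7"})

    def test_r9_rule(self):
        expr = parse_gpr("(g1 and g2) or (g3 and g4)")
        assert expr.kind == "or"
        assert all(c.kind == "and" for c in expr.children)

    def test_empty_rule(self):
        assert parse_gpr("").is_empty
        assert parse_gpr("   ").is_empty

    def test_precedence_and_binds_tighter(self):
        expr = parse_gpr("g1 and g2 or g3")
        assert expr.kind == "or"
        assert expr == parse_gpr("(g1 and g2) or g3")

    @pytest.mark.parametrize("text", ["g1 &  g2", "g1 && g2", "G1 AND g2"])
    def test_operator_synonyms(self, text):
        assert parse_gpr(text).kind == "and"

    def test_pipe_synonym(self):
        assert parse_gpr("g1 | g2").kind == "or"

    @pytest.mark.parametrize("text", ["(g1 and g2", "g1 or", "and g1",
                                      "g1 g2", "g1 and ()"])
    def test_errors_carry_position(self, text):
        with pytest.raises(GPRParseError) as err:
            parse_gpr(text)
        assert err.value.position >= 0
        assert "position" in str(err.value)

    def test_roundtrip_is_idempotent(self):
        for text in ["g0 and (g5 or g6 or g7)", "(g1 and g2) or (g3 and g4)",
                     "a or b and c", "((x))"]:
            expr = parse_gpr(text)
            assert parse_gpr(expr.to_string()) == expr

    def test_gene_identifiers_not_case_folded(self):
        expr = parse_gpr("Gene1 or gene1")
        assert expr.genes() == frozenset({"Gene1", "gene1"})


# ---------------------------------------------------------------------------
# to_dnf
# ---------------------------------------------------------------------------

class TestToDnf:
    def test_r9_summands(self):
        terms = to_dnf(parse_gpr("(g1 and g2) or (g3 and g4)"))
        assert set(terms) == fam({"g1", "g2"}, {"g3", "g4"})

    def test_single_literal(self):
        assert to_dnf(parse_gpr("g4")) == [frozenset({"g4"})]

    def test_distribution(self):
        # independently checked by truth-table equivalence over a, b, c
        terms = to_dnf(parse_gpr("(a or b) and c"))
        assert set(terms) == fam({"a", "c"}, {"b", "c"})

    def test_absorption(self):
        terms = to_dnf(parse_gpr("a or (a and b)"))
        assert set(terms) == fam({"a"})

    def test_explosion_guard(self):
        clauses = " and ".join(f"(x{i} or y{i})" for i in range(25))
        with pytest.raises(GPRComplexityError):
            to_dnf(parse_gpr(clauses), term_limit=1000)

    def test_empty_rule_rejected(self):
        with pytest.raises(GPRError):
            to_dnf(GPRExpr.empty())


# ---------------------------------------------------------------------------
# dnf_to_cnf_factors
# ---------------------------------------------------------------------------

class TestDnfToCnf:
    def test_r9_factors(self):
        result = dnf_to_cnf_factors([{"g1", "g2"}, {"g3", "g4"}])
        assert set(result) == fam({"g1", "g3"}, {"g1", "g4"},
                                  {"g2", "g3"}, {"g2", "g4"})

    def test_single_singleton(self):
        assert set(dnf_to_cnf_factors([{"a"}])) == fam({"a"})

    def test_two_overlapping_terms(self):
        # Expected values computed by brute-force enumeration of all
        # hitting sets of the two terms, reduced (see oracle below).
        result = dnf_to_cnf_factors([{"a", "b", "c", "d"},
                                     {"a", "b", "c", "e"}])
        assert set(result) == fam({"a"}, {"b"}, {"c"}, {"d", "e"})

    def test_matches_brute_force_oracle(self):
        terms = [frozenset({"a", "b", "c", "d"}), frozenset({"a", "b", "c", "e"})]
        genes = sorted(set().union(*terms))
        minimal = []
        for size in range(1, len(genes) + 1):
            for combo in combinations(genes, size):
                G = frozenset(combo)
                if all(G & t for t in terms) and \
                        not any(prev <= G for prev in minimal):
                    minimal.append(G)
        assert set(dnf_to_cnf_factors(terms)) == set(minimal)

    def test_empty_term_list_rejected(self):
        with pytest.raises(GPRError):
            dnf_to_cnf_factors([])

    def test_cap_is_exact_slice(self):
        terms = [{"a", "b"}, {"c", "d"}, {"a", "c"}]
        full = dnf_to_cnf_factors(terms)
        capped = dnf_to_cnf_factors(terms, cardinality_cap=1)
        assert set(capped) == {s for s in full if len(s) <= 1}


# ---------------------------------------------------------------------------
# reaction_gmcs / reduce_family / evaluate_gpr
# ---------------------------------------------------------------------------

R7 = "g0 and (g5 or g6 or g7)"


class TestReactionGmcs:
    def test_r7_uncapped(self):
        assert set(reaction_gmcs(parse_gpr(R7))) == fam({"g0"},
                                                        {"g5", "g6", "g7"})

    def test_r7_capped(self):
        assert set(reaction_gmcs(parse_gpr(R7), k=1)) == fam({"g0"})

    def test_empty_rule(self):
        family = reaction_gmcs(GPRExpr.empty())
        assert len(family) == 0

    def test_mixed_shape_rule(self):
        # neither pure DNF nor pure CNF: normalized via distribution
        expr = parse_gpr("a and (b or (c and d))")
        assert set(reaction_gmcs(expr)) == fam({"a"}, {"b", "c"}, {"b", "d"})


class TestReduceFamily:
    def test_superset_absorbed(self):
        assert set(reduce_family([{"g0"}, {"g0", "g1"}])) == fam({"g0"})

    def test_union_of_toy_reaction_families(self, toy_families):
        union = []
        for r in ["r0", "r1", "r4", "r7"]:
            union.extend(toy_families[r])
        assert set(reduce_family(union)) == fam({"g0"}, {"g1"}, {"g3"},
                                                {"g5", "g6", "g7"})

    def test_empty(self):
        assert len(reduce_family([])) == 0

    def test_idempotent_and_order_invariant(self):
        members = [{"a", "b"}, {"b"}, {"c", "d"}, {"b", "c"}]
        once = reduce_family(members)
        assert reduce_family(once.members) == once
        assert reduce_family(reversed(members)) == once

    def test_canonical_order(self):
        family = reduce_family([{"z"}, {"b", "c"}, {"a"}])
        assert [tuple(sorted(s)) for s in family] == [("a",), ("b", "c"), ("z",)]


class TestEvaluate:
    @pytest.mark.parametrize("knocked,expected", [
        ({"g0"}, False),
        ({"g5"}, True),
        (set(), True),
        ({"g5", "g6", "g7"}, False),
    ])
    def test_r7(self, knocked, expected):
        assert evaluate_gpr(parse_gpr(R7), knocked) is expected

    def test_empty_rule_always_true(self):
        assert evaluate_gpr(GPRExpr.empty(), {"g1"}) is True


class TestNormalFormShape:
    def test_flat_rules_are_both(self):
        for text in ["g1", "g1 or g2", "g1 and g2"]:
            expr = parse_gpr(text)
            assert is_dnf(expr) and is_cnf(expr)

    def test_r7_is_cnf_only(self):
        expr = parse_gpr(R7)
        assert is_cnf(expr) and not is_dnf(expr)

    def test_r9_is_dnf_only(self):
        expr = parse_gpr("(g1 and g2) or (g3 and g4)")
        assert is_dnf(expr) and not is_cnf(expr)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

def random_expr(draw, genes, depth):
    if depth == 0 or draw(st.booleans()):
        return GPRExpr.lit(draw(st.sampled_from(genes)))
    kind = draw(st.sampled_from(["and", "or"]))
    n_children = draw(st.integers(2, 3))
    children = [random_expr(draw, genes, depth - 1) for _ in range(n_children)]
    if kind == "and":
        return GPRExpr.conj(children)
    return GPRExpr.disj(children)


@st.composite
def gpr_exprs(draw, max_genes=12, max_depth=3):
    n = draw(st.integers(1, max_genes))
    genes = [f"g{i}" for i in range(n)]
    return random_expr(draw, genes, max_depth)


@settings(max_examples=120, deadline=None)
@given(gpr_exprs(max_genes=12))
def test_cnf_boolean_equivalence(expr):
    """The CNF built from the DNF factors evaluates identically to the
    original rule on every assignment of its genes."""
    genes = sorted(expr.genes())
    factors = reaction_gmcs(expr)
    for values in product([False, True], repeat=len(genes)):
        alive = {g for g, v in zip(genes, values) if v}
        knocked = set(genes) - alive
        original = evaluate_gpr(expr, knocked)
        via_cnf = all(bool(factor & alive) for factor in factors)
        assert original == via_cnf


@settings(max_examples=60, deadline=None)
@given(gpr_exprs(max_genes=8, max_depth=3))
def test_cut_set_characterization(expr):
    """reaction_gmcs equals the brute-force minimal falsifying knockouts."""
    genes = sorted(expr.genes())
    minimal = []
    for size in range(1, len(genes) + 1):
        for combo in combinations(genes, size):
            G = frozenset(combo)
            if any(prev <= G for prev in minimal):
                continue
            if not evaluate_gpr(expr, G):
                minimal.append(G)
    assert set(reaction_gmcs(expr)) == set(minimal)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=4),
                min_size=1, max_size=6))
def test_reduce_family_properties(members):
    family = reduce_family(members)
    # idempotent
    assert reduce_family(family.members) == family
    # order-invariant
    assert reduce_family(list(reversed(members))) == family
    # exactly the inclusion-minimal inputs survive
    sets = {frozenset(m) for m in members}
    expected = {s for s in sets if not any(t < s for t in sets)}
    assert set(family) == expected
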
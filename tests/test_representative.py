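"""Tests for the enumeration driver and its representative-subset logic."""

from __future__ import annotations

from itertools import combinations

import pytest

from gmcskit.gpr import GeneSetFamily
from gmcskit.hitting import minimal_hitting_sets
from gmcskit.representative import (
    GMCSCatalog,
    compute_gmcs,
    confirm_candidates,
    initialize,
    next_candidates,
)
from gmcskit.target import EnumeratedOracle, LPOracle, build_lethality_target, is_gcs

from conftest import SMALL_MODEL_GMCS, brute_force_gmcs, build_small_model

TOY_CATALOG = {
    frozenset({"g0"}),
    frozenset({"g1", "g2"}),
    frozenset({"g1", "g4"}),
    frozenset({"g3", "g4"}),
    frozenset({"g5", "g6", "g7"}),
}


def make_toy_oracle(toy_families, toy_supports, k=3, rng=None):
    return EnumeratedOracle(toy_supports, toy_families, k=k, rng=rng)


class TestCatalog:
    def test_reduced_invariant(self):
        catalog = GMCSCatalog()
        catalog.add({"g0"})
        with pytest.raises(ValueError, match="reduced"):
            catalog.add({"g0", "g1"})
        with pytest.raises(ValueError, match="reduced"):
            catalog.add({"g0"})

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            GMCSCatalog().add(set())

    def test_counts_and_slice(self):
        catalog = GMCSCatalog()
        for genes in TOY_CATALOG:
            catalog.add(genes)
        assert catalog.counts() == {1: 1, 2: 3, 3: 1}
        assert set(catalog.slice_upto(2)) == {G for G in TOY_CATALOG
                                              if len(G) <= 2}

    def test_canonical_iteration_order(self):
        catalog = GMCSCatalog()
        for genes in TOY_CATALOG:
            catalog.add(genes)
        listed = list(catalog)
        assert listed == sorted(listed, key=lambda s: (len(s),
                                                       tuple(sorted(s))))


class TestInitialize:
    def test_toy_seed(self, toy_families, toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        state = initialize(oracle, k_max=3)
        assert state.k_current == 1
        candidates = next_candidates(state, 1)
        assert set(candidates) == {frozenset({"g0"}), frozenset({"g1"}),
                                   frozenset({"g3"})}

    def test_unblockable_target_finishes_immediately(self):
        families = {"rX": GeneSetFamily()}
        oracle = EnumeratedOracle([{"rX"}], families)
        catalog = compute_gmcs(oracle, 3)
        assert len(catalog) == 0

    def test_seed_with_min_size_three(self):
        families = {"rA": GeneSetFamily([{"a", "b", "c"}])}
        oracle = EnumeratedOracle([{"rA"}], families)
        state = initialize(oracle, k_max=4)
        assert state.k_current == 3

    def test_invalid_k_max(self, toy_families, toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        with pytest.raises(ValueError):
            initialize(oracle, 0)


class TestPhases:
    def test_phase_one_confirms_g0_and_refutes_the_rest(self, toy_families,
                                                        toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        state = initialize(oracle, k_max=3)
        candidates = next_candidates(state, 1)
        confirm_candidates(state, candidates, 1)
        assert frozenset({"g0"}) in state.confirmed
        assert len(state.confirmed) == 1
        # every refuted candidate is refuted by some mode now in T'
        for G in candidates:
            if G not in state.confirmed:
                assert any(not m.family.contains_subset_of(G)
                           for m in state.modes)
        # the witness for {g1} must avoid every g1-dependent reaction
        supports = {m.support for m in state.modes}
        assert frozenset({"r0", "r3", "r6", "r7"}) in supports

    def test_witness_supports_stay_deduplicated(self, toy_families,
                                                toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        _, state = compute_gmcs(oracle, 3, return_state=True)
        supports = [m.support for m in state.modes]
        assert len(supports) == len(set(supports))
        # re-adding a known support is a no-op
        assert not state.add_mode(state.modes[0])

    def test_candidates_exclude_confirmed_supersets(self, toy_families,
                                                    toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        state = initialize(oracle, k_max=3)
        confirm_candidates(state, next_candidates(state, 1), 1)
        candidates = next_candidates(state, 2)
        assert all("g0" not in G for G in candidates)
        assert all(len(G) == 2 for G in candidates)

    def test_empty_candidate_family_is_noop(self, toy_families, toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        state = initialize(oracle, k_max=3)
        before = (len(state.modes), len(state.confirmed))
        confirm_candidates(state, GeneSetFamily(), 1)
        assert (len(state.modes), len(state.confirmed)) == before

    def test_singleton_only_family_gives_no_pairs(self):
        families = {"rA": GeneSetFamily([{"a"}, {"b"}])}
        oracle = EnumeratedOracle([{"rA"}], families)
        state = initialize(oracle, k_max=2)
        confirm_candidates(state, next_candidates(state, 1), 1)
        assert len(next_candidates(state, 2)) == 0


class TestComputeGmcs:
    def test_toy_full_catalog(self, toy_families, toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        catalog = compute_gmcs(oracle, 3)
        assert set(catalog) == TOY_CATALOG
        assert catalog.counts() == {1: 1, 2: 3, 3: 1}

    def test_toy_k_max_one(self, toy_families, toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports, k=1)
        catalog = compute_gmcs(oracle, 1)
        assert set(catalog) == {frozenset({"g0"})}

    def test_toy_completeness_vs_brute_force(self, toy_families,
                                             toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        catalog = compute_gmcs(oracle, 3)
        genes = {g for fam in toy_families.values()
                 for member in fam for g in member}
        reference = brute_force_gmcs(
            make_toy_oracle(toy_families, toy_supports).is_gcs, genes, 3)
        assert set(catalog) == reference

    def test_lp_model_completeness_and_soundness(self):
        model = build_small_model()
        target = build_lethality_target(model, p=0.01)
        oracle = LPOracle(target, k=3)
        catalog = compute_gmcs(oracle, 3)
        assert set(catalog) == SMALL_MODEL_GMCS
        # soundness + minimality, re-verified through the LP directly
        for G in catalog:
            assert is_gcs(target, G)
            for gene in G:
                assert not is_gcs(target, G - {gene})

    def test_lp_model_matches_brute_force(self):
        model = build_small_model()
        target = build_lethality_target(model, p=0.01)
        reference = brute_force_gmcs(lambda G: is_gcs(target, G),
                                     model.genes, 3)
        catalog = compute_gmcs(LPOracle(target, k=3), 3)
        assert set(catalog) == reference

    def test_representativeness_at_each_phase(self, toy_families,
                                              toy_supports):
        """After phase k, the hitting sets of T' at cap k equal the
        confirmed catalog's <=k slice."""
        oracle = make_toy_oracle(toy_families, toy_supports)

        def check(state, k):
            hitting = minimal_hitting_sets([m.family for m in state.modes], k)
            assert set(hitting) == set(state.confirmed.slice_upto(k))

        compute_gmcs(oracle, 3, phase_hook=check)

    def test_witness_order_robustness(self, toy_families, toy_supports):
        reference = compute_gmcs(make_toy_oracle(toy_families, toy_supports),
                                 3)
        for seed in range(8):
            oracle = make_toy_oracle(toy_families, toy_supports, rng=seed)
            assert set(compute_gmcs(oracle, 3)) == set(reference)

    def test_mode_growth_bounded_by_refutations(self, toy_families,
                                                toy_supports):
        oracle = make_toy_oracle(toy_families, toy_supports)
        _, state = compute_gmcs(oracle, 3, return_state=True)
        refuted = sum(p["candidates"] - p["confirmed"]
                      for p in state.phase_log)
        assert len(state.modes) <= 1 + refuted
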
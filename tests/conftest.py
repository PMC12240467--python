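"""Shared fixtures: the ten-reaction toy instance and a small LP model."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
import scipy.sparse as sp

from gmcskit.gpr import GeneSetFamily, parse_gpr
from gmcskit.model_io import MetabolicModel, toy_fixture


@pytest.fixture(scope="session")
def toy():
    """(reaction_families, supports, meta) of the worked-example network."""
    return toy_fixture()


@pytest.fixture(scope="session")
def toy_families(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_supports(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_mode_families(toy_families, toy_supports):
    from gmcskit.hitting import mode_gmcs

    return [mode_gmcs(s, toy_families) for s in toy_supports]


def build_small_model() -> MetabolicModel:
    """Hand-built 6-gene network with a known gMCS catalog.

    Metabolites A, B, C; two parallel A->B routes (an isozyme pair and a
    single-gene reaction, one of them reversible), a complex-catalyzed
    B->C step and an unguarded export used as the biomass reaction:

        IN:  -> A            rule gI
        P1:  A -> B          rule g1 or g2
        P2:  A <-> B         rule g3
        CX:  B -> C          rule g4 and g5
        OUT: C ->  (biomass) no rule

    Growth requires IN, (P1 or P2), CX and OUT, so the minimal blocking
    sets are {gI}, {g4}, {g5} and {g1, g2, g3}.
    """
    metabolites = ["A", "B", "C"]
    reactions = ["IN", "P1", "P2", "CX", "OUT"]
    S = sp.csr_matrix(np.array([
        #  IN   P1   P2   CX  OUT
        [1.0, -1.0, -1.0, 0.0, 0.0],   # A
        [0.0, 1.0, 1.0, -1.0, 0.0],    # B
        [0.0, 0.0, 0.0, 1.0, -1.0],    # C
    ]))
    lower = np.array([0.0, 0.0, -10.0, 0.0, 0.0])
    upper = np.array([10.0, 10.0, 10.0, 10.0, 10.0])
    rules = {
        "IN": "gI",
        "P1": "g1 or g2",
        "P2": "g3",
        "CX": "g4 and g5",
        "OUT": "",
    }
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lower=lower,
        upper=upper,
        gpr={r: parse_gpr(rule) for r, rule in rules.items()},
        genes=["gI", "g1", "g2", "g3", "g4", "g5"],
        biomass_reaction="OUT",
        name="small",
    )


SMALL_MODEL_GMCS = {
    frozenset({"gI"}),
    frozenset({"g4"}),
    frozenset({"g5"}),
    frozenset({"g1", "g2", "g3"}),
}

#: Supports of the two elementary growth routes of the small model.
SMALL_MODEL_SUPPORTS = (
    frozenset({"IN", "P1", "CX", "OUT"}),
    frozenset({"IN", "P2", "CX", "OUT"}),
)


@pytest.fixture(scope="session")
def small_model():
    return build_small_model()


def brute_force_hitting_sets(families, k):
    """Oracle: every gene subset of size <= k with the hitting property,
    reduced to the inclusion-minimal ones.  Exponential; tiny inputs only."""
    genes = sorted({g for fam in families for member in fam for g in member})

    def hits_all(G):
        G = frozenset(G)
        return all(any(member <= G for member in fam) for fam in families)

    found = []
    for size in range(0, k + 1):
        for combo in combinations(genes, size):
            G = frozenset(combo)
            if hits_all(G) and not any(prev <= G for prev in found):
                found.append(G)
    return set(found)


def brute_force_gmcs(is_gcs, genes, k_max):
    """Oracle: test every gene subset of size <= k_max with ``is_gcs`` and
    keep the inclusion-minimal cut sets."""
    found = []
    for size in range(1, k_max + 1):
        for combo in combinations(sorted(genes), size):
            G = frozenset(combo)
            if any(prev <= G for prev in found):
                continue
            if is_gcs(G):
                found.append(G)
    return set(found)


def random_family(rng, genes, max_members=5, max_size=3) -> GeneSetFamily:
    n_members = rng.integers(1, max_members + 1)
    members = []
    for _ in range(n_members):
        size = rng.integers(1, max_size + 1)
        members.append(frozenset(rng.choice(genes, size=size, replace=False)))
    return GeneSetFamily(members)
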
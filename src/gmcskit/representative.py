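"""Enumeration driver: representative mode subsets and the gMCS catalog.

The driver maintains a growing list of modes T' drawn from the target
region.  At each cardinality phase k it computes the minimal hitting sets
of size k across the modes' gene-support families, filters out candidates
containing an already confirmed cut set, and submits the survivors to the
witness oracle: a candidate with no surviving mode is a confirmed gMCS of
the target, otherwise the returned witness joins T' (deduplicated by
support).  Once phase k completes, T' is k-representative — its hitting
sets of size <= k coincide with the target's gMCSs of size <= k — so the
next phase can again work on T' alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .gpr import GeneSetFamily
from .hitting import Mode, minimal_hitting_sets

__all__ = [
    "GMCSCatalog",
    "RepresentativeState",
    "initialize",
    "next_candidates",
    "confirm_candidates",
    "compute_gmcs",
]

logger = logging.getLogger(__name__)


class GMCSCatalog:
    """All confirmed gMCSs of a target, indexed by cardinality.

    The catalog is globally reduced: no member contains another, across
    cardinalities.  Iteration order is canonical (cardinality, then the
    sorted gene tuple), so serialized output is deterministic.
    """

    def __init__(self, target_name: str = "",
                 default_classification: str = "lethal"):
        self.target_name = target_name
        self.default_classification = default_classification
        self._sets: set = set()
        self._classification: dict = {}

    # -- mutation -----------------------------------------------------------

    def add(self, G: Iterable[str], classification: Optional[str] = None) -> None:
        G = frozenset(G)
        if not G:
            raise ValueError("cannot add the empty gene set")
        for member in self._sets:
            if member <= G or G <= member:
                raise ValueError(
                    "catalog must stay reduced: "
                    f"{sorted(G)} vs existing {sorted(member)}")
        self._sets.add(G)
        if classification is not None:
            self._classification[G] = classification

    def classify(self, G: Iterable[str], classification: str) -> None:
        G = frozenset(G)
        if G not in self._sets:
            raise KeyError(f"{sorted(G)} is not in the catalog")
        self._classification[G] = classification

    # -- queries ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(sorted(self._sets, key=lambda s: (len(s), tuple(sorted(s)))))

    def __contains__(self, G: Iterable[str]) -> bool:
        return frozenset(G) in self._sets

    def __eq__(self, other: object) -> bool:
        if isinstance(other, GMCSCatalog):
            return (self._sets == other._sets
                    and self.target_name == other.target_name
                    and {G: self.classification_of(G) for G in self._sets}
                    == {G: other.classification_of(G) for G in other._sets})
        return NotImplemented

    def classification_of(self, G: Iterable[str]) -> str:
        return self._classification.get(frozenset(G),
                                        self.default_classification)

    @property
    def by_cardinality(self) -> dict:
        out: dict = {}
        for G in self._sets:
            out.setdefault(len(G), []).append(G)
        return {k: GeneSetFamily._from_reduced(sets, cardinality_cap=k)
                for k, sets in sorted(out.items())}

    def counts(self) -> dict:
        """Number of gMCSs per cardinality."""
        out: dict = {}
        for G in self._sets:
            out[len(G)] = out.get(len(G), 0) + 1
        return dict(sorted(out.items()))

    def contains_subset_of(self, G: Iterable[str]) -> bool:
        G = frozenset(G)
        return any(member <= G for member in self._sets)

    def slice_upto(self, k: int) -> GeneSetFamily:
        """The confirmed gMCSs of size <= k, as a family."""
        return GeneSetFamily._from_reduced(
            (s for s in self._sets if len(s) <= k), cardinality_cap=k)

    def to_records(self) -> list:
        return [
            {
                "cardinality": len(G),
                "genes": sorted(G),
                "target": self.target_name,
                "classification": self.classification_of(G),
            }
            for G in self
        ]


@dataclass
class RepresentativeState:
    """Driver state: the mode list T', confirmed catalog and current phase."""

    oracle: object
    k_max: int
    modes: list = field(default_factory=list)
    confirmed: GMCSCatalog = field(default_factory=GMCSCatalog)
    k_current: int = 1
    finished: bool = False
    phase_log: list = field(default_factory=list)
    _supports: set = field(default_factory=set)

    def add_mode(self, mode: Mode) -> bool:
        """Append a witness unless its support is already present."""
        if mode.support in self._supports:
            return False
        self._supports.add(mode.support)
        self.modes.append(mode)
        return True


def initialize(oracle, k_max: int, target_name: str = "") -> RepresentativeState:
    """Seed the driver with a first witness of the (wild-type) target.

    The starting phase is the smallest member size of the seed mode's
    family; an empty family means no mode of the target can be blocked
    genetically, so the enumeration terminates immediately with an empty
    catalog.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    state = RepresentativeState(oracle=oracle, k_max=k_max,
                                confirmed=GMCSCatalog(target_name=target_name))
    seed = oracle.initial_mode()
    if seed is None or not seed.family:
        state.finished = True
        state.k_current = k_max + 1
        return state
    state.add_mode(seed)
    state.k_current = seed.family.min_size()
    if state.k_current > k_max:
        state.finished = True
    return state


def next_candidates(state: RepresentativeState, k_next: int) -> GeneSetFamily:
    """Candidate gMCSs of size exactly ``k_next``.

    Minimal hitting sets across the current modes' families at cap
    ``k_next``, minus any set containing a confirmed gMCS.  Because T' is
    (k_next-1)-representative when this runs, every smaller hitting set is
    already confirmed and falls to the containment filter; the survivors
    all have size k_next.
    """
    hitting = minimal_hitting_sets(
        [m.family for m in state.modes], k_next,
        exclude_supersets_of=list(state.confirmed))
    kept = [G for G in hitting
            if len(G) == k_next and not state.confirmed.contains_subset_of(G)]
    return GeneSetFamily._from_reduced(kept, cardinality_cap=k_next)


class _ActiveCandidates:
    """Id-bitmap filter over a fixed candidate list.

    Keeps, per gene, the bitmap of candidate ids containing it; refuting a
    whole mode family then runs as big-integer AND/OR instead of per-
    candidate containment probes.
    """

    def __init__(self, candidates):
        self.candidates = list(candidates)
        self.alive = (1 << len(self.candidates)) - 1
        self.index: dict = {}
        for i, G in enumerate(self.candidates):
            bit = 1 << i
            for gene in G:
                self.index[gene] = self.index.get(gene, 0) | bit

    def drop_refuted_by(self, family) -> None:
        """Remove candidates that do not hit ``family`` (not cut sets)."""
        hit = 0
        for member in family:
            sel = self.alive & ~hit
            if sel == 0:
                break
            for gene in member:
                sel &= self.index.get(gene, 0)
                if sel == 0:
                    break
            hit |= sel
        self.alive &= hit

    def is_active(self, i: int) -> bool:
        return bool(self.alive >> i & 1)


def confirm_candidates(state: RepresentativeState,
                       candidates: GeneSetFamily, k: int) -> RepresentativeState:
    """Resolve each size-k candidate: confirm it or add its witness to T'.

    Candidates are processed in canonical order for reproducibility.  A
    witness added earlier in the phase may already refute a later
    candidate — candidates hit every phase-start mode by construction, so
    each new mode's family is applied once as a bitmap filter over the
    remaining candidates, and only survivors reach the LP.  Each refuted
    candidate therefore contributes at most one new mode (witnesses are
    deduplicated by support).
    """
    confirmed_here = 0
    lp_refuted = 0
    active = _ActiveCandidates(candidates)
    for i, G in enumerate(active.candidates):
        if not active.is_active(i):
            continue
        witness = state.oracle.find_witness(G)
        if witness is None:
            state.confirmed.add(G)
            confirmed_here += 1
        else:
            lp_refuted += 1
            state.add_mode(witness)
            active.drop_refuted_by(witness.family)
            if active.is_active(i):
                raise AssertionError(
                    "oracle returned a witness that does not refute the "
                    f"candidate {sorted(G)}")
    refuted_cheap = len(active.candidates) - confirmed_here - lp_refuted
    entry = {
        "k": k,
        "candidates": len(candidates),
        "confirmed": confirmed_here,
        "refuted_without_lp": refuted_cheap,
        "modes": len(state.modes),
        "lp_calls": getattr(state.oracle, "lp_calls", None),
    }
    state.phase_log.append(entry)
    logger.info("phase k=%(k)d: %(candidates)d candidates, "
                "%(confirmed)d confirmed, |T'|=%(modes)d, "
                "lp_calls=%(lp_calls)s", entry)
    return state


def compute_gmcs(oracle, k_max: int, target_name: str = "",
                 phase_hook=None,
                 return_state: bool = False):
    """Enumerate all gMCSs of the oracle's target up to size ``k_max``.

    Runs initialize -> (candidates -> confirm) per cardinality phase.
    Phases below the seed mode's minimum family member size are provably
    empty (every cut set of the target contains a member of the seed
    mode's family) and are skipped.  Deterministic for a deterministic
    oracle.  ``phase_hook(state, k)`` is called after each completed phase.
    """
    from time import perf_counter

    state = initialize(oracle, k_max, target_name=target_name)
    while not state.finished and state.k_current <= k_max:
        t0 = perf_counter()
        candidates = next_candidates(state, state.k_current)
        t1 = perf_counter()
        confirm_candidates(state, candidates, state.k_current)
        if state.phase_log:
            state.phase_log[-1]["berge_s"] = round(t1 - t0, 2)
            state.phase_log[-1]["confirm_s"] = round(perf_counter() - t1, 2)
            logger.info("phase k=%d timings: berge %.1fs, confirm %.1fs",
                        state.k_current, t1 - t0, perf_counter() - t1)
        if phase_hook is not None:
            phase_hook(state, state.k_current)
        state.k_current += 1
    state.finished = True
    if return_state:
        return state.confirmed, state
    return state.confirmed
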
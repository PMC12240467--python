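"""Generalized minimal hitting sets across per-mode gene-set families.

A gene set ``G`` "hits" a mode when some member of the mode's gMCS family
is contained in ``G``; the genetic minimal cut sets of a mode collection
are exactly the inclusion-minimal gene sets hitting every mode.  They are
enumerated incrementally, Berge-style: fold the mode families in one at a
time, keeping the working collection reduced and pruned to the requested
cardinality cap.

Internally gene sets are encoded as integer bitmasks over the gene universe
of the instance, which makes subset tests and membership hashing cheap at
genome scale; the public API speaks :class:`~gmcskit.gpr.GeneSetFamily`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

from .gpr import GeneSetFamily

__all__ = [
    "Mode",
    "mode_gmcs",
    "is_cutset_for_mode",
    "berge_step",
    "minimal_hitting_sets",
]

#: Flux magnitudes below this are treated as zero when extracting supports.
DEFAULT_SUPPORT_TOL = 1e-6


@dataclass(frozen=True)
class Mode:
    """A feasible flux state summarized by its active-reaction support.

    ``family`` is the mode's gene-support family (the reduced union of the
    per-reaction gMCS families over the support, possibly cardinality
    capped); ``flux`` optionally retains the witnessing flux values.
    """

    support: frozenset
    family: GeneSetFamily
    flux: Optional[Mapping[str, float]] = None

    @classmethod
    def from_flux(cls, flux: Mapping[str, float],
                  reaction_families: Mapping[str, GeneSetFamily],
                  k: Optional[int] = None,
                  support_tol: float = DEFAULT_SUPPORT_TOL) -> "Mode":
        support = frozenset(r for r, v in flux.items() if abs(v) > support_tol)
        family = mode_gmcs(support, reaction_families, k)
        return cls(support=support, family=family, flux=dict(flux))


def mode_gmcs(support: Iterable[str],
              reaction_families: Mapping[str, GeneSetFamily],
              k: Optional[int] = None) -> GeneSetFamily:
    """gMCS family of a mode: reduced union of the per-reaction families
    over its support, capped at ``k`` if given.

    An empty result means the mode cannot be blocked genetically.  Unknown
    reaction identifiers raise ``KeyError``.
    """
    support = frozenset(support)
    missing = [r for r in support if r not in reaction_families]
    if missing:
        raise KeyError(f"unknown reaction(s) in support: {sorted(missing)}")
    return GeneSetFamily.merge(
        (reaction_families[r] for r in sorted(support)), cardinality_cap=k)


def is_cutset_for_mode(G: Iterable[str], family: GeneSetFamily) -> bool:
    """True iff some family member is a subset of ``G``."""
    return family.contains_subset_of(G)


# ---------------------------------------------------------------------------
# Bitmask engine
# ---------------------------------------------------------------------------

class _MaskCodec:
    """Bijection between gene-identifier sets and integer bitmasks."""

    def __init__(self, genes: Iterable[str]):
        self.genes: list[str] = sorted(set(genes))
        self.bit: dict[str, int] = {g: 1 << i for i, g in enumerate(self.genes)}

    @classmethod
    def for_families(cls, families: Iterable[GeneSetFamily]) -> "_MaskCodec":
        genes: set[str] = set()
        for family in families:
            for member in family:
                genes.update(member)
        return cls(genes)

    def encode(self, geneset: Iterable[str]) -> int:
        mask = 0
        for gene in geneset:
            mask |= self.bit[gene]
        return mask

    def decode(self, mask: int) -> frozenset:
        out = []
        while mask:
            bit = mask & -mask
            out.append(self.genes[bit.bit_length() - 1])
            mask ^= bit
        return frozenset(out)


def _bit_list(mask: int) -> list[int]:
    bits = []
    while mask:
        bit = mask & -mask
        bits.append(bit)
        mask ^= bit
    return bits


def _submasks(mask: int) -> tuple[int, ...]:
    """All submasks of ``mask`` (including 0 and ``mask`` itself), smallest
    first.  Intended for masks with few set bits (<= cardinality cap)."""
    bits = _bit_list(mask)
    out = []
    for size in range(len(bits) + 1):
        for combo in combinations(bits, size):
            sub = 0
            for bit in combo:
                sub |= bit
            out.append(sub)
    return tuple(out)


def _berge_step_masks(current: set[int], member_list: Sequence[int],
                      member_set: frozenset, k: int,
                      submask_cache: dict,
                      forbidden: frozenset = frozenset()) -> set[int]:
    """One Berge update over bitmask-encoded sets; ``current`` reduced.

    Working sets with a submask in ``forbidden`` are discarded: a final
    transversal free of forbidden subsets has an ancestor chain of its own
    subsets, none of which can contain a forbidden set either, so eager
    pruning loses nothing.
    """
    survivors: list[int] = []
    failing: list[int] = []
    for G in current:
        subs = submask_cache.get(G)
        if subs is None:
            subs = _submasks(G)
            submask_cache[G] = subs
        if any(sub in member_set for sub in subs):
            survivors.append(G)
        else:
            failing.append(G)
    children: set[int] = set()
    for G in failing:
        for member in member_list:
            union = G | member
            if union.bit_count() <= k:
                children.add(union)
    # Survivors are mutually minimal and never absorbed by children (a child
    # strictly inside a survivor would make its failing parent a subset of
    # that survivor, contradicting reducedness of `current`); children only
    # need checking against survivors and smaller children.
    kept = set(survivors)
    for child in sorted(children, key=int.bit_count):
        if child in kept:
            continue
        subs = submask_cache.get(child)
        if subs is None:
            subs = _submasks(child)
            submask_cache[child] = subs
        if forbidden and any(sub in forbidden for sub in subs):
            continue
        if not any(sub in kept for sub in subs[:-1]):  # proper submasks only
            kept.add(child)
    return kept


def berge_step(current: GeneSetFamily, mode_family: GeneSetFamily,
               k: int) -> GeneSetFamily:
    """Update the working family of minimal hitting sets with one new mode.

    Every set already hitting ``mode_family`` survives; each failing set is
    replaced by its unions with the mode's members, pruned first by the
    cardinality cap ``k`` and then by minimality.  Initialization is the
    family containing the empty set.
    """
    codec = _MaskCodec.for_families((current, mode_family))
    current_masks = {mask for G in current
                     if (mask := codec.encode(G)).bit_count() <= k}
    member_list = [codec.encode(m) for m in mode_family]
    member_set = frozenset(member_list)
    result = _berge_step_masks(set(current_masks), member_list, member_set,
                               k, {})
    return GeneSetFamily._from_reduced((codec.decode(m) for m in result),
                                       cardinality_cap=k)


class _FoldEngine:
    """Incremental Berge fold with an inverted gene -> id-bitmap index.

    Working sets are gene bitmasks stored in id slots; per-family hit
    detection runs as big-integer AND/OR over the id bitmaps (one AND per
    member gene), so the scan over the working collection is carried out
    in C rather than per-set Python probes.  Only failing sets are touched
    individually (children generation + minimality pruning).
    """

    def __init__(self, k: int, forbidden: frozenset):
        self.k = k
        self.forbidden = forbidden
        self.slots: list = [0]          # id -> mask (the {∅} initialization)
        self.alive: int = 1             # id bitmap of live sets
        self.alive_masks: set = {0}
        self.index: dict = {}           # gene bit -> id bitmap
        self.submask_cache: dict = {}

    def _submasks_of(self, mask: int):
        subs = self.submask_cache.get(mask)
        if subs is None:
            subs = _submasks(mask)
            self.submask_cache[mask] = subs
        return subs

    def _add(self, mask: int) -> None:
        slot = len(self.slots)
        self.slots.append(mask)
        bit = 1 << slot
        self.alive |= bit
        self.alive_masks.add(mask)
        for gene_bit in _bit_list(mask):
            self.index[gene_bit] = self.index.get(gene_bit, 0) | bit

    def _compact(self) -> None:
        live = [mask for slot, mask in enumerate(self.slots)
                if self.alive >> slot & 1]
        self.slots = []
        self.alive = 0
        self.alive_masks = set()
        self.index = {}
        for mask in live:
            self._add(mask)

    def hit_bitmap(self, member_list: Sequence[int]) -> int:
        """Id bitmap of live sets containing at least one member."""
        hit = 0
        alive = self.alive
        index = self.index
        for member in member_list:
            sel = alive & ~hit
            if sel == 0:
                break
            for gene_bit in _bit_list(member):
                sel &= index.get(gene_bit, 0)
                if sel == 0:
                    break
            hit |= sel
        return hit

    def fold(self, member_list: Sequence[int], member_set: frozenset) -> None:
        failing = self.alive & ~self.hit_bitmap(member_list)
        if failing == 0:
            return
        # drop the failing sets and grow their pruned children
        self.alive &= ~failing
        children: set = set()
        remaining = failing
        while remaining:
            bit = remaining & -remaining
            remaining ^= bit
            mask = self.slots[bit.bit_length() - 1]
            self.alive_masks.discard(mask)
            for member in member_list:
                union = mask | member
                if union.bit_count() <= self.k:
                    children.add(union)
        kept = self.alive_masks
        forbidden = self.forbidden
        for child in sorted(children, key=int.bit_count):
            if child in kept:
                continue
            subs = self._submasks_of(child)
            if forbidden and any(sub in forbidden for sub in subs):
                continue
            if any(sub in kept for sub in subs[:-1]):  # proper submasks
                continue
            self._add(child)
        if len(self.slots) > 4 * max(len(self.alive_masks), 1024):
            self._compact()

    def result_masks(self) -> set:
        return set(self.alive_masks)


def minimal_hitting_sets(families: Sequence[GeneSetFamily],
                         k: int,
                         exclude_supersets_of: Iterable[frozenset] = ()
                         ) -> GeneSetFamily:
    """All inclusion-minimal gene sets of size <= ``k`` containing a member
    of every family.

    The result is independent of the family order.  A family with no
    members of size <= k (in particular an empty family) cannot be hit
    within the cap, so the result is then empty.

    ``exclude_supersets_of`` drops every output set containing one of the
    given gene sets; the filter is applied eagerly inside the fold, which
    changes nothing about the surviving output (any subset of a surviving
    set is itself free of the excluded sets) but prunes the working
    collection substantially.
    """
    if k < 1:
        raise ValueError("cardinality cap k must be >= 1")
    exclude = {frozenset(e) for e in exclude_supersets_of}

    def is_excluded(member: frozenset) -> bool:
        # Members containing an excluded set can neither make a surviving
        # working set hit their family (the working set would contain the
        # excluded set too) nor spawn unpruned children, so dropping them
        # is exact.
        if not exclude:
            return False
        items = sorted(member)
        for size in range(1, len(items) + 1):
            for combo in combinations(items, size):
                if frozenset(combo) in exclude:
                    return True
        return False

    live = [[m for m in family if not is_excluded(m)] for family in families]
    # narrow the bit universe to genes of live members: working sets only
    # ever contain those, and narrow masks hash faster
    codec = _MaskCodec(g for members in live for m in members for g in m)
    forbidden = frozenset(
        codec.encode(e) for e in exclude
        if all(g in codec.bit for g in e))
    # fold identical families once, most constraining (fewest members) first
    encoded: dict = {}
    for members in live:
        masks = [codec.encode(m) for m in members]
        encoded.setdefault(frozenset(masks), masks)
    engine = _FoldEngine(k, forbidden)
    for member_set in sorted(encoded, key=len):
        engine.fold(encoded[member_set], member_set)
        if not engine.alive_masks:
            break
    return GeneSetFamily._from_reduced(
        (codec.decode(m) for m in engine.result_masks()), cardinality_cap=k)
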
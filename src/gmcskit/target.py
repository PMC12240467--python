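"""Target flux regions, LP feasibility knockout tests and witness modes.

A target region is T = {v | S·v = 0, l <= v <= u, A·v >= b}.  A gene set G
is a genetic cut set for T exactly when the LP obtained by fixing the
bounds of every G-blocked reaction to [0, 0] is infeasible; when it is
feasible, any feasible point is a witness mode of T surviving the knockout.
Knockouts are applied by bound-fixing (never column deletion) and the
biomass threshold p·biomass_max is fixed once from the wild type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .gpr import GeneSetFamily, evaluate_gpr, reaction_gmcs
from .hitting import DEFAULT_SUPPORT_TOL, Mode, is_cutset_for_mode, mode_gmcs
from .model_io import MetabolicModel

__all__ = [
    "SolverError",
    "TargetSpec",
    "max_biomass",
    "build_lethality_target",
    "build_coupling_target",
    "blocked_reactions",
    "is_gcs",
    "find_witness",
    "classify_intervention",
    "LPOracle",
    "EnumeratedOracle",
    "BIOMASS_BLOCKING",
    "COUPLING_ENFORCING",
]

logger = logging.getLogger(__name__)

BIOMASS_BLOCKING = "biomass-blocking"
COUPLING_ENFORCING = "coupling-enforcing"

#: Treat optima below this magnitude as zero growth.
_GROWTH_TOL = 1e-9


class SolverError(RuntimeError):
    """LP backend reported a numerical failure (never a silent boolean)."""


@dataclass
class TargetSpec:
    """A model plus extra linear rows A·v >= b defining the target region.

    ``biomass_max`` is the wild-type optimum used to scale the biomass
    fraction ``p``; it is computed once and cached here.
    """

    model: MetabolicModel
    A: sp.csr_matrix
    b: np.ndarray
    name: str = "target"
    p: float = 0.01
    biomass_max: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.p <= 1.0):
            raise ValueError("biomass fraction p must lie in (0, 1]")
        self.b = np.asarray(self.b, dtype=float)
        if self.A.shape != (self.b.size, self.model.n_reactions):
            raise ValueError("extra-row matrix shape does not match model")


# ---------------------------------------------------------------------------
# LP core (scipy HiGHS backend)
# ---------------------------------------------------------------------------

_STATUS_NAMES = {
    0: "optimal",
    1: "iteration limit",
    2: "infeasible",
    3: "unbounded",
    4: "numerical failure",
}


def _solve(model: MetabolicModel,
           A: Optional[sp.csr_matrix] = None,
           b: Optional[np.ndarray] = None,
           maximize: Optional[int] = None,
           blocked: Iterable[str] = ()):
    """Solve the (in)feasibility LP; returns (feasible, x, objective).

    ``maximize`` is a reaction index to maximize, or None for a pure
    feasibility solve (objective f = 0).  ``blocked`` reactions get bounds
    fixed to [0, 0].  Raises :class:`SolverError` on anything other than a
    clean optimal/infeasible verdict.
    """
    n = model.n_reactions
    lower = model.lower
    upper = model.upper
    blocked = list(blocked)
    if blocked:
        lower = lower.copy()
        upper = upper.copy()
        for rid in blocked:
            i = model.reaction_index(rid)
            lower[i] = 0.0
            upper[i] = 0.0
    c = np.zeros(n)
    if maximize is not None:
        c[maximize] = -1.0
    kwargs = {}
    if A is not None and A.shape[0] > 0:
        kwargs["A_ub"] = -A
        kwargs["b_ub"] = -np.asarray(b, dtype=float)
    res = linprog(c, A_eq=model.S, b_eq=np.zeros(model.S.shape[0]),
                  bounds=np.column_stack([lower, upper]),
                  method="highs", **kwargs)
    if res.status == 0:
        objective = -res.fun if maximize is not None else 0.0
        return True, res.x, objective
    if res.status == 2:
        return False, None, None
    raise SolverError(
        f"LP solver failed: {_STATUS_NAMES.get(res.status, res.status)} "
        f"({res.message})")


def _solve_sparse(model: MetabolicModel,
                  A: Optional[sp.csr_matrix] = None,
                  b: Optional[np.ndarray] = None,
                  blocked: Iterable[str] = (),
                  weights: Optional[np.ndarray] = None):
    """Feasibility solve minimizing a weighted L1 norm of the flux vector.

    Splits v = x+ - x- with sign-consistent bounds and minimizes
    sum(w·(x+ + x-)); the optimum is a parsimonious point of the same
    region, whose small (weighted) support keeps witness-mode families
    small.  Returns (feasible, v) with v of length n.
    """
    n = model.n_reactions
    lower = model.lower
    upper = model.upper
    blocked = list(blocked)
    if blocked:
        lower = lower.copy()
        upper = upper.copy()
        for rid in blocked:
            i = model.reaction_index(rid)
            lower[i] = 0.0
            upper[i] = 0.0
    pos_lo = np.maximum(lower, 0.0)
    pos_hi = np.maximum(upper, 0.0)
    neg_lo = np.maximum(-upper, 0.0)
    neg_hi = np.maximum(-lower, 0.0)
    bounds = np.column_stack([np.concatenate([pos_lo, neg_lo]),
                              np.concatenate([pos_hi, neg_hi])])
    S2 = sp.hstack([model.S, -model.S], format="csr")
    kwargs = {}
    if A is not None and A.shape[0] > 0:
        A2 = sp.hstack([A, -A], format="csr")
        kwargs["A_ub"] = -A2
        kwargs["b_ub"] = -np.asarray(b, dtype=float)
    if weights is None:
        weights = np.ones(n)
    res = linprog(np.concatenate([weights, weights]), A_eq=S2,
                  b_eq=np.zeros(model.S.shape[0]),
                  bounds=bounds, method="highs", **kwargs)
    if res.status == 0:
        return True, res.x[:n] - res.x[n:]
    if res.status == 2:
        return False, None
    raise SolverError(
        f"LP solver failed: {_STATUS_NAMES.get(res.status, res.status)} "
        f"({res.message})")


def max_biomass(model: MetabolicModel) -> float:
    """Optimum of max v_biomass subject to S·v = 0 and the flux bounds."""
    if model.biomass_reaction is None:
        raise ValueError("model has no biomass (objective) reaction set")
    idx = model.reaction_index(model.biomass_reaction)
    try:
        feasible, _, value = _solve(model, maximize=idx)
    except SolverError as err:
        if "unbounded" in str(err):
            raise SolverError("biomass maximization is unbounded") from err
        raise
    if not feasible:
        raise SolverError("model is infeasible: no flux vector satisfies "
                          "steady state within the bounds")
    return value


def build_lethality_target(model: MetabolicModel, p: float = 0.01,
                           name: str = "lethality") -> TargetSpec:
    """Target of all modes with biomass >= p times the wild-type maximum."""
    bm = max_biomass(model)
    if bm <= _GROWTH_TOL:
        raise ValueError("maximal biomass flux is zero: no growth to block")
    n = model.n_reactions
    idx = model.reaction_index(model.biomass_reaction)
    A = sp.csr_matrix(([1.0], ([0], [idx])), shape=(1, n))
    return TargetSpec(model=model, A=A, b=np.array([p * bm]), name=name,
                      p=p, biomass_max=bm)


def build_coupling_target(model: MetabolicModel, product_reaction: str,
                          p: float = 0.01,
                          name: Optional[str] = None) -> TargetSpec:
    """Target of growth-without-production modes: biomass >= p·max, v_r = 0.

    The equality is encoded as the two inequality rows v_r >= 0 and
    -v_r >= 0 so the region stays uniformly of the form A·v >= b.  gMCSs of
    this target are interventions eliminating growth without flux through
    ``product_reaction``.
    """
    bm = max_biomass(model)
    if bm <= _GROWTH_TOL:
        raise ValueError("maximal biomass flux is zero: no growth to block")
    n = model.n_reactions
    bio = model.reaction_index(model.biomass_reaction)
    prod = model.reaction_index(product_reaction)
    A = sp.csr_matrix(
        ([1.0, 1.0, -1.0], ([0, 1, 2], [bio, prod, prod])), shape=(3, n))
    b = np.array([p * bm, 0.0, 0.0])
    target = TargetSpec(model=model, A=A, b=b,
                        name=name or f"couple:{product_reaction}",
                        p=p, biomass_max=bm)
    feasible, _, _ = _solve(model, A=A, b=b)
    if not feasible:
        raise ValueError(
            "wild-type target region is empty: every growth state already "
            f"forces flux through {product_reaction}")
    return target


def blocked_reactions(model: MetabolicModel, G: Iterable[str]) -> frozenset:
    """Reactions whose rule evaluates false under knockout of ``G``.

    Rule-less reactions are never blocked.  Genes absent from the model
    raise ``ValueError``.
    """
    G = frozenset(G)
    unknown = G - set(model.genes)
    if unknown:
        raise ValueError(f"unknown gene(s): {sorted(unknown)}")
    return frozenset(
        r for r in model.reactions if not evaluate_gpr(model.gpr[r], G))


def is_gcs(target: TargetSpec, G: Iterable[str]) -> bool:
    """True iff the knockout LP over the target region is infeasible."""
    blocked = blocked_reactions(target.model, G)
    feasible, _, _ = _solve(target.model, A=target.A, b=target.b,
                            blocked=blocked)
    return not feasible


def find_witness(target: TargetSpec, G: Iterable[str],
                 reaction_families: Optional[Mapping[str, GeneSetFamily]] = None,
                 k: Optional[int] = None,
                 support_tol: float = DEFAULT_SUPPORT_TOL) -> Optional[Mode]:
    """A mode of the target surviving knockout ``G``, or None iff is_gcs.

    The support is extracted at ``support_tol`` and the mode's gene-support
    family computed at cap ``k`` from ``reaction_families`` (derived from
    the model's rules when not supplied).
    """
    blocked = blocked_reactions(target.model, G)
    feasible, x, _ = _solve(target.model, A=target.A, b=target.b,
                            blocked=blocked)
    if not feasible:
        return None
    if reaction_families is None:
        reaction_families = target.model.reaction_families(k)
    flux = {r: float(x[i]) for i, r in enumerate(target.model.reactions)}
    return Mode.from_flux(flux, reaction_families, k=k,
                          support_tol=support_tol)


def classify_intervention(target: TargetSpec, G: Iterable[str]) -> str:
    """Category of a confirmed coupling-target gMCS.

    Maximize biomass under knockout ``G`` (without the extra target rows):
    ``biomass-blocking`` when the optimum falls below p·biomass_max,
    ``coupling-enforcing`` otherwise (growth persists but only with
    production).
    """
    blocked = blocked_reactions(target.model, G)
    idx = target.model.reaction_index(target.model.biomass_reaction)
    feasible, _, value = _solve(target.model, maximize=idx, blocked=blocked)
    if not feasible or value < target.p * target.biomass_max:
        return BIOMASS_BLOCKING
    return COUPLING_ENFORCING


# ---------------------------------------------------------------------------
# Persistent warm-started LP (vendored HiGHS inside scipy)
# ---------------------------------------------------------------------------

class _PersistentWitnessLP:
    """Weighted-L1 feasibility model kept resident in the solver.

    Splits v = x+ - x- with sign-consistent bounds and minimizes
    sum(w·(x+ + x-)) over the target region; per-candidate knockouts only
    flip column bounds, so consecutive solves warm-start from the previous
    basis.  Built on the HiGHS binding vendored inside scipy
    (``scipy.optimize._highspy``); callers fall back to one-shot scipy
    solves when the binding is unavailable.
    """

    def __init__(self, model: MetabolicModel, A: sp.csr_matrix,
                 b: np.ndarray, weights: np.ndarray):
        from scipy.optimize._highspy import _core as _hs

        self._hs = _hs
        self.n = n = model.n_reactions
        self.pos_lo = np.maximum(model.lower, 0.0)
        self.pos_hi = np.maximum(model.upper, 0.0)
        self.neg_lo = np.maximum(-model.upper, 0.0)
        self.neg_hi = np.maximum(-model.lower, 0.0)
        stacked = sp.vstack([
            sp.hstack([model.S, -model.S]),
            sp.hstack([A, -A]),
        ]).tocsc()
        lp = _hs.HighsLp()
        lp.num_col_ = 2 * n
        lp.num_row_ = stacked.shape[0]
        lp.col_cost_ = np.concatenate([weights, weights])
        lp.col_lower_ = np.concatenate([self.pos_lo, self.neg_lo])
        lp.col_upper_ = np.concatenate([self.pos_hi, self.neg_hi])
        big = 1e30
        lp.row_lower_ = np.concatenate(
            [np.zeros(model.S.shape[0]), np.asarray(b, dtype=float)])
        lp.row_upper_ = np.concatenate(
            [np.zeros(model.S.shape[0]), np.full(A.shape[0], big)])
        matrix = _hs.HighsSparseMatrix()
        matrix.format_ = _hs.MatrixFormat.kColwise
        matrix.num_col_ = 2 * n
        matrix.num_row_ = stacked.shape[0]
        matrix.start_ = stacked.indptr.astype(np.int64)
        matrix.index_ = stacked.indices.astype(np.int32)
        matrix.value_ = stacked.data.astype(float)
        lp.a_matrix_ = matrix
        self.highs = _hs._Highs()
        self.highs.setOptionValue("output_flag", False)
        status = self.highs.passModel(lp)
        if status != _hs.HighsStatus.kOk:
            raise SolverError(f"could not load LP into HiGHS: {status}")

    def solve(self, blocked_indices):
        """Returns (feasible, v) with knockout bounds applied transiently."""
        _hs = self._hs
        n = self.n
        for i in blocked_indices:
            self.highs.changeColBounds(i, 0.0, 0.0)
            self.highs.changeColBounds(n + i, 0.0, 0.0)
        try:
            self.highs.run()
            status = self.highs.getModelStatus()
            if status == _hs.HighsModelStatus.kOptimal:
                x = np.asarray(self.highs.getSolution().col_value)
                return True, x[:n] - x[n:]
            if status == _hs.HighsModelStatus.kInfeasible:
                return False, None
            raise SolverError(f"LP solver failed: HiGHS status {status}")
        finally:
            for i in blocked_indices:
                self.highs.changeColBounds(
                    i, float(self.pos_lo[i]), float(self.pos_hi[i]))
                self.highs.changeColBounds(
                    n + i, float(self.neg_lo[i]), float(self.neg_hi[i]))


# ---------------------------------------------------------------------------
# Witness oracles
# ---------------------------------------------------------------------------

class LPOracle:
    """Witness oracle backed by LP feasibility on a :class:`TargetSpec`.

    Contract: ``is_gcs(G)`` true implies ``find_witness(G)`` is None;
    otherwise a surviving mode of the target is returned.  Per-reaction
    gMCS families are computed lazily at cap ``k`` and cached.
    """

    def __init__(self, target: TargetSpec, k: Optional[int] = None,
                 support_tol: float = DEFAULT_SUPPORT_TOL,
                 sparse_witness: bool = True):
        self.target = target
        self.k = k
        self.support_tol = support_tol
        self.sparse_witness = sparse_witness
        self.lp_calls = 0
        self._families: dict = {}
        # penalize only reactions whose activity affects gene families
        self._witness_weights = np.array(
            [0.0 if target.model.gpr[r].is_empty else 1.0
             for r in target.model.reactions])
        self._persistent: Optional[_PersistentWitnessLP] = None
        try:
            self._persistent = _PersistentWitnessLP(
                target.model, target.A, target.b, self._witness_weights)
        except ImportError:  # older scipy without the vendored binding
            logger.info("persistent HiGHS unavailable; using one-shot solves")

    def _family(self, reaction_id: str) -> GeneSetFamily:
        family = self._families.get(reaction_id)
        if family is None:
            expr = self.target.model.gpr[reaction_id]
            family = reaction_gmcs(expr, self.k)
            self._families[reaction_id] = family
        return family

    def _families_for(self, support: Iterable[str]) -> dict:
        return {r: self._family(r) for r in support}

    def is_gcs(self, G: Iterable[str]) -> bool:
        self.lp_calls += 1
        if self._persistent is not None:
            blocked = blocked_reactions(self.target.model, G)
            index = self.target.model.reaction_index
            feasible, _ = self._persistent.solve([index(r) for r in blocked])
            return not feasible
        return is_gcs(self.target, G)

    def find_witness(self, G: Iterable[str]) -> Optional[Mode]:
        self.lp_calls += 1
        blocked = blocked_reactions(self.target.model, G)
        if self._persistent is not None:
            index = self.target.model.reaction_index
            feasible, x = self._persistent.solve([index(r) for r in blocked])
        elif self.sparse_witness:
            feasible, x = _solve_sparse(self.target.model, A=self.target.A,
                                        b=self.target.b, blocked=blocked,
                                        weights=self._witness_weights)
        else:
            feasible, x, _ = _solve(self.target.model, A=self.target.A,
                                    b=self.target.b, blocked=blocked)
        if not feasible:
            return None
        model = self.target.model
        support = frozenset(
            r for i, r in enumerate(model.reactions)
            if abs(x[i]) > self.support_tol)
        flux = {r: float(x[model.reaction_index(r)]) for r in support}
        family = mode_gmcs(support, self._families_for(support), self.k)
        return Mode(support=support, family=family, flux=flux)

    def initial_mode(self) -> Optional[Mode]:
        """Witness of the wild type (empty knockout); None never occurs for
        a validly constructed target, but infeasibility raises loudly."""
        mode = self.find_witness(frozenset())
        if mode is None:
            raise SolverError(
                f"wild-type target LP for {self.target.name!r} is infeasible")
        return mode


class EnumeratedOracle:
    """Witness oracle over an explicit list of mode supports.

    Used for worked examples and brute-force cross-checks where the target
    is given by enumeration instead of stoichiometry.  ``rng`` (a
    numpy Generator or seed) permutes the witness search order, which must
    not change any final catalog.
    """

    def __init__(self, supports: Sequence[Iterable[str]],
                 reaction_families: Mapping[str, GeneSetFamily],
                 k: Optional[int] = None, rng=None):
        self.k = k
        self.reaction_families = dict(reaction_families)
        self.modes = [
            Mode(support=frozenset(s),
                 family=mode_gmcs(s, self.reaction_families, k))
            for s in supports
        ]
        if not self.modes:
            raise ValueError("enumerated oracle requires at least one mode")
        if rng is not None:
            rng = np.random.default_rng(rng)
            order = rng.permutation(len(self.modes))
            self.modes = [self.modes[i] for i in order]
        self.lp_calls = 0  # counts membership checks, for parity in logs

    def is_gcs(self, G: Iterable[str]) -> bool:
        self.lp_calls += 1
        G = frozenset(G)
        return all(is_cutset_for_mode(G, m.family) for m in self.modes)

    def find_witness(self, G: Iterable[str]) -> Optional[Mode]:
        self.lp_calls += 1
        G = frozenset(G)
        for mode in self.modes:
            if not is_cutset_for_mode(G, mode.family):
                return mode
        return None

    def initial_mode(self) -> Mode:
        return self.modes[0]
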
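"""Reading constraint-based metabolic models and writing result catalogs.

SBML (level 3 + fbc) and COBRA JSON files are read through cobrapy and
converted to a lightweight in-memory representation carrying exactly the
data the cut-set machinery needs: the stoichiometric matrix over internal
metabolites, flux bounds, parsed gene-protein rules and the biomass
(objective) reaction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp

from .gpr import GeneSetFamily, GPRExpr, parse_gpr, reaction_gmcs

__all__ = [
    "MetabolicModel",
    "read_model",
    "write_model_json",
    "apply_medium",
    "read_medium_tsv",
    "toy_fixture",
    "write_catalog",
    "read_catalog",
]


@dataclass
class MetabolicModel:
    """Constraint-based model data: S·v = 0 with l <= v <= u.

    Rows of ``S`` cover internal metabolites only; irreversibility is
    encoded by nonnegative lower bounds.  Flux units are whatever the
    source model declares and are treated as opaque.
    """

    metabolites: list
    reactions: list
    S: sp.csr_matrix
    lower: np.ndarray
    upper: np.ndarray
    gpr: dict
    genes: list
    biomass_reaction: Optional[str] = None
    name: str = ""
    _index: Optional[dict] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        m, n = self.S.shape
        if m != len(self.metabolites) or n != len(self.reactions):
            raise ValueError("stoichiometric matrix shape does not match "
                             f"{len(self.metabolites)} metabolites x "
                             f"{len(self.reactions)} reactions")
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != (n,) or self.upper.shape != (n,):
            raise ValueError("bound vectors must have one entry per reaction")
        bad = np.nonzero(self.lower > self.upper)[0]
        if bad.size:
            raise ValueError(
                f"lower bound exceeds upper bound for {self.reactions[bad[0]]}")
        gene_universe = set(self.genes)
        referenced = set()
        for expr in self.gpr.values():
            referenced.update(expr.genes())
        extra = referenced - gene_universe
        if extra:
            self.genes = self.genes + sorted(extra)
        if (self.biomass_reaction is not None
                and self.biomass_reaction not in self.reactions):
            raise ValueError(
                f"biomass reaction {self.biomass_reaction!r} not in model")

    # -- lookups ------------------------------------------------------------

    def reaction_index(self, reaction_id: str) -> int:
        if self._index is None:
            self._index = {r: i for i, r in enumerate(self.reactions)}
        try:
            return self._index[reaction_id]
        except KeyError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def bounds_of(self, reaction_id: str) -> Tuple[float, float]:
        i = self.reaction_index(reaction_id)
        return float(self.lower[i]), float(self.upper[i])

    def with_bounds(self, bounds: Mapping[str, Tuple[float, float]]
                    ) -> "MetabolicModel":
        """Copy of the model with the given per-reaction bounds replaced."""
        lower = self.lower.copy()
        upper = self.upper.copy()
        for reaction_id, (lb, ub) in bounds.items():
            i = self.reaction_index(reaction_id)
            lower[i], upper[i] = lb, ub
        return replace(self, lower=lower, upper=upper, _index=None)

    def reaction_families(self, k: Optional[int] = None) -> dict:
        """Per-reaction gMCS families from the parsed rules (cap ``k``)."""
        return {r: reaction_gmcs(self.gpr[r], k) for r in self.reactions}


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _from_cobra(cobra_model, biomass_reaction: Optional[str]) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = sp.csr_matrix(create_stoichiometric_matrix(cobra_model,
                                                   array_type="lil"))
    reactions = [r.id for r in cobra_model.reactions]
    metabolites = [m.id for m in cobra_model.metabolites]
    lower = np.array([r.lower_bound for r in cobra_model.reactions], float)
    upper = np.array([r.upper_bound for r in cobra_model.reactions], float)
    gpr = {}
    declared = {g.id for g in cobra_model.genes}
    for r in cobra_model.reactions:
        rule = r.gene_reaction_rule or ""
        expr = parse_gpr(rule)
        undeclared = expr.genes() - declared
        if undeclared:
            warnings.warn(
                f"reaction {r.id}: rule references gene products not "
                f"declared in the model ({sorted(undeclared)}); parsed from "
                "the raw rule string")
        gpr[r.id] = expr
    if biomass_reaction is None:
        coeffs = {
            r.id: r.objective_coefficient
            for r in cobra_model.reactions if r.objective_coefficient
        }
        if len(coeffs) == 1:
            biomass_reaction = next(iter(coeffs))
        elif len(coeffs) > 1:
            raise ValueError(
                "model declares multiple objective reactions "
                f"({sorted(coeffs)}); pass biomass_reaction explicitly")
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        S=S,
        lower=lower,
        upper=upper,
        gpr=gpr,
        genes=sorted(g.id for g in cobra_model.genes),
        biomass_reaction=biomass_reaction,
        name=cobra_model.id or "",
    )


def read_model(path: Union[str, Path], format: str = "auto",
               biomass_reaction: Optional[str] = None) -> MetabolicModel:
    """Read an SBML (+fbc) or COBRA JSON model file.

    ``format`` is ``"sbml"``, ``"json"`` or ``"auto"`` (by extension;
    ``.xml``/``.sbml``/``.xml.gz`` -> SBML, ``.json`` -> JSON).  The
    objective reaction becomes the biomass reaction unless overridden.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffixes = "".join(path.suffixes).lower()
        if suffixes.endswith((".json",)):
            format = "json"
        elif any(s in suffixes for s in (".xml", ".sbml")):
            format = "sbml"
        else:
            raise ValueError(f"cannot infer model format from {path.name!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # cobra is chatty about SBML quirks
        if format == "sbml":
            cobra_model = cobra.io.read_sbml_model(str(path))
        elif format == "json":
            cobra_model = cobra.io.load_json_model(str(path))
        else:
            raise ValueError(f"unknown model format {format!r}")
    return _from_cobra(cobra_model, biomass_reaction)


def write_model_json(model: MetabolicModel, path: Union[str, Path]) -> None:
    """Serialize to COBRA JSON (compartment-less placeholder metabolites).

    Only the fields read back by :func:`read_model` are meaningful; the
    round trip preserves stoichiometry, bounds, rules and the objective.
    """
    S = model.S.tocsc()
    reactions = []
    for j, rid in enumerate(model.reactions):
        col = S.getcol(j).tocoo()
        mets = {model.metabolites[i]: float(v) for i, v in zip(col.row, col.data)}
        reactions.append({
            "id": rid,
            "name": rid,
            "metabolites": mets,
            "lower_bound": float(model.lower[j]),
            "upper_bound": float(model.upper[j]),
            "gene_reaction_rule": model.gpr[rid].to_string(),
            "objective_coefficient":
                1.0 if rid == model.biomass_reaction else 0.0,
        })
    doc = {
        "id": model.name or "model",
        "version": "1",
        "compartments": {"c": "cytosol"},
        "metabolites": [
            {"id": m, "name": m, "compartment": "c", "charge": 0, "formula": ""}
            for m in model.metabolites
        ],
        "reactions": reactions,
        "genes": [{"id": g, "name": g} for g in model.genes],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def apply_medium(model: MetabolicModel,
                 closed_exchanges: Iterable[str] = (),
                 bounds: Optional[Mapping[str, Tuple[float, float]]] = None
                 ) -> MetabolicModel:
    """Model with the listed exchange reactions closed (bounds [0, 0]) and/or
    with explicit bound pairs assigned.  Unknown reactions raise."""
    updates = {r: (0.0, 0.0) for r in closed_exchanges}
    if bounds:
        updates.update({r: (float(lb), float(ub))
                        for r, (lb, ub) in bounds.items()})
    if not updates:
        return model
    return model.with_bounds(updates)


def read_medium_tsv(path: Union[str, Path]) -> dict:
    """Medium file: TSV with columns reaction id, lower bound, upper bound."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed medium line: {line!r}")
        out[parts[0]] = (float(parts[1]), float(parts[2]))
    return out


# ---------------------------------------------------------------------------
# Toy fixture
# ---------------------------------------------------------------------------

TOY_RULES = {
    "r0": "g0",
    "r1": "g1",
    "r2": "g1",
    "r3": "g2",
    "r4": "g3",
    "r5": "g4",
    "r6": "g4",
    "r7": "g0 and (g5 or g6 or g7)",
    "r8": "g8",
    "r9": "(g1 and g2) or (g3 and g4)",
}

TOY_SUPPORTS = (
    frozenset({"r0", "r1", "r4", "r7"}),
    frozenset({"r0", "r2", "r5", "r7"}),
    frozenset({"r0", "r3", "r6", "r7"}),
)


def toy_fixture():
    """Ten-reaction demonstration network with nine genes and three modes.

    Returns ``(reaction_families, mode_supports, metadata)``: per-reaction
    gMCS families computed from the rule table, the three explicit mode
    supports, and a metadata dict with the raw rule strings and gene list.
    No stoichiometry is attached — the hitting-set layer consumes the
    supports directly.  (The narrative this table comes from describes the
    network as having eight reactions; the rule table defines ten, r0-r9,
    and all ten are included here.)
    """
    families = {r: reaction_gmcs(parse_gpr(rule))
                for r, rule in TOY_RULES.items()}
    genes = sorted({g for rule in TOY_RULES.values()
                    for g in parse_gpr(rule).genes()})
    meta = {
        "rules": dict(TOY_RULES),
        "genes": genes,
        "n_modes": len(TOY_SUPPORTS),
    }
    return families, list(TOY_SUPPORTS), meta


# ---------------------------------------------------------------------------
# Catalog output
# ---------------------------------------------------------------------------

_CATALOG_HEADER = ("cardinality", "genes", "target", "classification")


def write_catalog(catalog, path: Union[str, Path], format: str = "auto") -> None:
    """Write a gMCS catalog as TSV or JSON (deterministic record order).

    One record per gene set: cardinality, sorted comma-joined genes, target
    name and classification (``lethal`` for lethality targets,
    ``biomass-blocking``/``coupling-enforcing`` for coupling targets).
    """
    path = Path(path)
    if format == "auto":
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    records = catalog.to_records()
    if format == "tsv":
        lines = ["\t".join(_CATALOG_HEADER)]
        for rec in records:
            lines.append("\t".join(
                (str(rec["cardinality"]), ",".join(rec["genes"]),
                 rec["target"], rec["classification"])))
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        doc = {"target": catalog.target_name, "gmcs": records}
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown catalog format {format!r}")


def read_catalog(path: Union[str, Path]):
    """Read back a JSON catalog written by :func:`write_catalog`."""
    from .representative import GMCSCatalog

    doc = json.loads(Path(path).read_text())
    catalog = GMCSCatalog(target_name=doc.get("target", ""))
    for rec in doc["gmcs"]:
        classification = rec.get("classification") or None
        catalog.add(frozenset(rec["genes"]), classification=classification)
    return catalog
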
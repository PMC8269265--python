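"""Domain types for stoichiometric species models, readers/writers and plain FBA.

A :class:`SpeciesModel` is a minimal constraint-based model: metabolites,
reactions with flux bounds (mmol·gDW⁻¹·h⁻¹), and one biomass reaction whose
flux is the growth rate (h⁻¹).  Exchange reactions follow the dominant
SBML/FBC convention: a single boundary metabolite with stoichiometry
``{met_e: -1}``, negative flux = uptake, positive flux = secretion.  The
medium sets exchange lower bounds to ``-(uptake limit)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

logger = logging.getLogger(__name__)

#: default magnitude for unconstrained internal fluxes
DEFAULT_BOUND = 1000.0

CATEGORIES = ("amino-acid", "carbon", "nucleotide", "vitamin-cofactor",
              "inorganic", "other")


class ModelFormatError(ValueError):
    """Raised when a model file violates the expected schema/format."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    category: str = "other"

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ModelFormatError(
                f"metabolite {self.id}: unknown category {self.category!r}")


@dataclass
class Reaction:
    id: str
    stoich: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False

    def __post_init__(self):
        if self.lower_bound > self.upper_bound:
            raise ModelFormatError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")
        zero = [m for m, c in self.stoich.items() if c == 0.0]
        for m in zero:  # canonical form: zero coefficients are dropped
            logger.warning("reaction %s: dropping zero coefficient for %s",
                           self.id, m)
            del self.stoich[m]
        if self.is_exchange and len(self.stoich) != 1:
            raise ModelFormatError(
                f"exchange reaction {self.id} must touch exactly one "
                f"metabolite, got {sorted(self.stoich)}")

    @property
    def exchange_metabolite(self) -> str:
        if not self.is_exchange:
            raise ValueError(f"{self.id} is not an exchange reaction")
        return next(iter(self.stoich))


@dataclass
class SpeciesModel:
    """One organism's stoichiometric network."""

    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction_id: str

    def __post_init__(self):
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelFormatError(f"model {self.id}: duplicate metabolite "
                                   f"ids {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelFormatError(f"model {self.id}: duplicate reaction ids")
        if self.biomass_reaction_id not in set(rxn_ids):
            raise ModelFormatError(
                f"model {self.id}: biomass reaction "
                f"{self.biomass_reaction_id!r} not found")
        declared = set(met_ids)
        for r in self.reactions:
            missing = set(r.stoich) - declared
            if missing:
                raise ModelFormatError(
                    f"model {self.id}: reaction {r.id} references undeclared "
                    f"metabolites {sorted(missing)}")

    # -- convenience ---------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def exchange_reactions(self) -> List[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    @property
    def exchangeable_metabolites(self) -> List[str]:
        return [r.exchange_metabolite for r in self.exchange_reactions]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    def stoichiometric_matrix(self):
        """Sparse S (metabolites × reactions) plus index maps."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(self.reactions):
            for m, c in r.stoich.items():
                rows.append(met_index[m])
                cols.append(j)
                vals.append(c)
        S = sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)))
        return S, met_index, {r.id: j for j, r in enumerate(self.reactions)}

    def copy(self) -> "SpeciesModel":
        return SpeciesModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[Reaction(r.id, dict(r.stoich), r.lower_bound,
                                r.upper_bound, r.is_exchange)
                       for r in self.reactions],
            biomass_reaction_id=self.biomass_reaction_id)


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective: Optional[float] = None
    fluxes: Optional[Dict[str, float]] = None


_LINPROG_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def fba(model: SpeciesModel, medium) -> FBAResult:
    """Maximize biomass flux subject to S·v = 0 and bounds.

    ``medium`` maps boundary metabolite ids to maximal uptake rates; exchange
    reactions for unlisted metabolites get uptake bound 0 (secretion stays
    allowed).  An infeasible LP yields ``status="infeasible"``; a model that
    simply cannot grow (zero vector feasible) returns objective 0 with
    ``status="optimal"``.
    """
    S, _, rxn_index = model.stoichiometric_matrix()
    n = len(model.reactions)
    bounds = []
    for r in model.reactions:
        if r.is_exchange:
            met = r.exchange_metabolite
            lb = -float(medium.uptake_limits.get(met, 0.0))
            ub = float(medium.secretion_limits.get(met, r.upper_bound))
            bounds.append((lb, ub))
        else:
            bounds.append((r.lower_bound, r.upper_bound))
    c = np.zeros(n)
    c[rxn_index[model.biomass_reaction_id]] = -1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                  method="highs")
    status = _LINPROG_STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return FBAResult(status=status)
    fluxes = {r.id: float(res.x[j]) for r, j in
              zip(model.reactions, range(n))}
    return FBAResult(status="optimal", objective=float(-res.fun),
                     fluxes=fluxes)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"id", "metabolites", "reactions", "biomass_reaction_id"}
_MET_KEYS = {"id", "name", "compartment", "category"}
_RXN_KEYS = {"id", "stoich", "lb", "ub", "is_exchange"}


def write_model_json(model: SpeciesModel, path) -> None:
    doc = {
        "id": model.id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment,
             "category": m.category} for m in model.metabolites],
        "reactions": [
            {"id": r.id,
             "stoich": {k: r.stoich[k] for k in sorted(r.stoich)},
             "lb": r.lower_bound, "ub": r.upper_bound,
             "is_exchange": r.is_exchange} for r in model.reactions],
        "biomass_reaction_id": model.biomass_reaction_id,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> SpeciesModel:
    with open(path) as fh:
        doc = json.load(fh)
    missing = _MODEL_KEYS - set(doc)
    if missing:
        raise ModelFormatError(
            f"{path}: missing keys {sorted(missing)}")
    mets = []
    for d in doc["metabolites"]:
        miss = _MET_KEYS - set(d)
        if miss:
            raise ModelFormatError(f"{path}: metabolite entry missing keys "
                                   f"{sorted(miss)}")
        mets.append(Metabolite(**d))
    rxns = []
    for d in doc["reactions"]:
        miss = _RXN_KEYS - set(d)
        if miss:
            raise ModelFormatError(f"{path}: reaction entry missing keys "
                                   f"{sorted(miss)}")
        rxns.append(Reaction(id=d["id"], stoich=dict(d["stoich"]),
                             lower_bound=d["lb"], upper_bound=d["ub"],
                             is_exchange=d["is_exchange"]))
    return SpeciesModel(id=doc["id"], metabolites=mets, reactions=rxns,
                        biomass_reaction_id=doc["biomass_reaction_id"])


# ---------------------------------------------------------------------------
# SBML L3 + FBC via cobrapy
# ---------------------------------------------------------------------------

def write_sbml(model: SpeciesModel, path) -> None:
    """Write the model as SBML Level 3 with FBC bounds and objective."""
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, name=m.name or m.id,
                                compartment=m.compartment)
        cmets[m.id] = cmet
    for r in model.reactions:
        crxn = cobra.Reaction(r.id)
        crxn.lower_bound = r.lower_bound
        crxn.upper_bound = r.upper_bound
        cm.add_reactions([crxn])
        crxn.add_metabolites({cmets[m]: c for m, c in r.stoich.items()})
    cm.objective = model.biomass_reaction_id
    cobra.io.write_sbml_model(cm, str(path))


def read_sbml(path, category_table: Optional[Dict[str, str]] = None
              ) -> SpeciesModel:
    """Read an SBML L3+FBC model into a :class:`SpeciesModel`.

    Exchange reactions are flagged by single-metabolite stoichiometry.
    Metabolite categories come from ``category_table`` (defaulting to the
    packaged lookup, matched on the id stripped of its compartment suffix).
    """
    import cobra
    from cobra.util.solver import linear_reaction_coefficients

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ModelFormatError(f"{path}: SBML parse failure: {exc}") from exc
    coeffs = linear_reaction_coefficients(cm)
    if not coeffs:
        raise ModelFormatError(f"{path}: model declares no objective")
    biomass = max(coeffs, key=lambda r: abs(coeffs[r])).id
    if category_table is None:
        category_table = load_category_table()
    mets, rxns = [], []
    for m in cm.metabolites:
        mets.append(Metabolite(
            id=m.id, name=m.name or "", compartment=m.compartment or "c",
            category=lookup_category(m.id, category_table)))
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(Reaction(id=r.id, stoich=stoich,
                             lower_bound=float(r.lower_bound),
                             upper_bound=float(r.upper_bound),
                             is_exchange=len(stoich) == 1))
    return SpeciesModel(id=cm.id or "model", metabolites=mets,
                        reactions=rxns, biomass_reaction_id=biomass)


# ---------------------------------------------------------------------------
# Metabolite category lookup (editable TSV shipped with the package)
# ---------------------------------------------------------------------------

def load_category_table() -> Dict[str, str]:
    from importlib import resources

    table: Dict[str, str] = {}
    ref = resources.files("symcomm").joinpath("data/metabolite_categories.tsv")
    with ref.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            base, cat = line.split("\t")[:2]
            table[base] = cat
    return table


def lookup_category(met_id: str, table: Dict[str, str]) -> str:
    """Category of a metabolite id; compartment suffixes are stripped."""
    base = met_id
    for suffix in ("_c", "_e", "_u", "_p"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    return table.get(base, "other")


def assign_categories(model: SpeciesModel,
                      table: Optional[Dict[str, str]] = None) -> SpeciesModel:
    if table is None:
        table = load_category_table()
    for m in model.metabolites:
        m.category = lookup_category(m.id, table)
    return model
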
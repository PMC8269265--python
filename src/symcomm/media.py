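"""Nutrient regimes: medium files, application to communities, tiered media.

Three tiers mirror a host-diet gradient: *minimal* carries only primary
carbon/nitrogen/sulfur/phosphorus sources (glucose, glycerol, ammonia,
sulfate, phosphate), *base* adds every pool auxotrophy at a limiting rate so
all species grow in isolation, and *rich* multiplies base by an excess
factor and opens every transportable metabolite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .model_core import SpeciesModel, fba

logger = logging.getLogger(__name__)


class MediumError(ValueError):
    pass


#: default primary C/N/S/P sources and uptake limits (mmol·gDW⁻¹·h⁻¹)
DEFAULT_PRIMARY_SOURCES: Dict[str, float] = {
    "glc_e": 10.0,
    "glyc_e": 10.0,
    "nh4_e": 1000.0,
    "so4_e": 1000.0,
    "po4_e": 1000.0,
}


@dataclass
class Medium:
    """Map from environment metabolite to maximal community uptake rate."""

    name: str
    uptake_limits: Dict[str, float]
    secretion_limits: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for met, lim in self.uptake_limits.items():
            if lim < 0:
                raise MediumError(f"medium {self.name}: negative uptake "
                                  f"limit for {met}: {lim}")

    def scaled(self, factor: float, name: Optional[str] = None) -> "Medium":
        return Medium(name or self.name,
                      {m: v * factor for m, v in self.uptake_limits.items()},
                      dict(self.secretion_limits))


def load_medium(path, name: Optional[str] = None) -> Medium:
    """Read a TSV with columns metabolite_id, uptake_limit[, secretion_limit]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"metabolite_id", "uptake_limit"}
    if not required <= set(df.columns):
        raise MediumError(f"{path}: missing columns "
                          f"{sorted(required - set(df.columns))}")
    if df["metabolite_id"].duplicated().any():
        dup = sorted(df.loc[df["metabolite_id"].duplicated(), "metabolite_id"])
        raise MediumError(f"{path}: duplicate metabolite rows {dup}")
    uptake = dict(zip(df["metabolite_id"], df["uptake_limit"].astype(float)))
    secretion = {}
    if "secretion_limit" in df.columns:
        sub = df.dropna(subset=["secretion_limit"])
        secretion = dict(zip(sub["metabolite_id"],
                             sub["secretion_limit"].astype(float)))
    return Medium(name or str(path), uptake, secretion)


def save_medium(medium: Medium, path) -> None:
    mets = sorted(set(medium.uptake_limits) | set(medium.secretion_limits))
    rows = [{"metabolite_id": m,
             "uptake_limit": medium.uptake_limits.get(m, 0.0),
             "secretion_limit": medium.secretion_limits.get(m)}
            for m in mets]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_tiers_yaml(media: Dict[str, Medium], path) -> None:
    """Write a {tier: {metabolite: uptake limit}} YAML of tier definitions."""
    import yaml

    doc = {name: {"uptake_limits": dict(sorted(m.uptake_limits.items())),
                  "secretion_limits": dict(sorted(
                      m.secretion_limits.items()))}
           for name, m in sorted(media.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def apply_medium(community, medium: Medium):
    """Set community-exchange bounds from the medium (in place, returned).

    Lower bound = −uptake limit for listed metabolites, 0 for unlisted;
    upper bound from secretion overrides, else the default secretion cap.
    Medium entries matching no community exchange are logged and ignored.
    """
    matched = set()
    for lumen_met, rxn in community.community_exchanges.items():
        env_met = community.env_metabolite_of[lumen_met]
        if env_met in medium.uptake_limits:
            rxn.lower_bound = -float(medium.uptake_limits[env_met])
            matched.add(env_met)
        else:
            rxn.lower_bound = 0.0
        if env_met in medium.secretion_limits:
            rxn.upper_bound = float(medium.secretion_limits[env_met])
            matched.add(env_met)
    unmatched = (set(medium.uptake_limits) | set(medium.secretion_limits)) \
        - matched
    if unmatched:
        logger.info("medium %s: %d entries match no community exchange: %s",
                    medium.name, len(unmatched), sorted(unmatched))
    community.medium_name = medium.name
    return community


# ---------------------------------------------------------------------------
# Auxotrophy detection and tier construction
# ---------------------------------------------------------------------------

def detect_auxotrophies(model: SpeciesModel, minimal: Medium,
                        ample: float = 1000.0,
                        growth_tol: float = 1e-6) -> List[str]:
    """Smallest supplement set restoring growth on the minimal medium.

    Single-metabolite rescue sweep first; if no single candidate rescues,
    fall back to a greedy prune from the full candidate set (covers species
    requiring several non-substitutable metabolites at once).
    """
    res = fba(model, minimal)
    if res.status == "optimal" and (res.objective or 0.0) > growth_tol:
        return []
    candidates = sorted(set(model.exchangeable_metabolites)
                        - set(minimal.uptake_limits))

    def grows(extra: List[str]) -> bool:
        limits = dict(minimal.uptake_limits)
        limits.update({m: ample for m in extra})
        r = fba(model, Medium("probe", limits))
        return r.status == "optimal" and (r.objective or 0.0) > growth_tol

    for met in candidates:
        if grows([met]):
            return [met]
    if not grows(candidates):
        raise MediumError(
            f"species {model.id}: unsatisfiable auxotrophy — no combination "
            f"of exchangeable metabolites {candidates} restores growth")
    required = list(candidates)
    for met in list(candidates):  # greedy prune, deterministic order
        trial = [m for m in required if m != met]
        if grows(trial):
            required = trial
    return required


def make_tiered_media(pool: List[SpeciesModel],
                      primary_sources: Optional[Dict[str, float]] = None,
                      aux_rate: float = 1.0,
                      excess: float = 10.0,
                      growth_tol: float = 1e-6) -> Dict[str, Medium]:
    """Build {minimal, base, rich} media for a species pool.

    base = minimal ∪ (union of pool auxotrophies at ``aux_rate``);
    rich = base with all limits × ``excess`` plus every transportable
    metabolite of the pool at ``aux_rate × excess``.
    """
    primary = dict(primary_sources or DEFAULT_PRIMARY_SOURCES)
    minimal = Medium("minimal", primary)
    aux_union: List[str] = []
    for model in pool:
        for met in detect_auxotrophies(model, minimal,
                                       growth_tol=growth_tol):
            if met not in aux_union:
                aux_union.append(met)
    base_limits = dict(primary)
    base_limits.update({m: aux_rate for m in aux_union})
    base = Medium("base", base_limits)
    rich_limits = {m: v * excess for m, v in base_limits.items()}
    transportable = sorted({m for model in pool
                            for m in model.exchangeable_metabolites})
    for met in transportable:
        rich_limits.setdefault(met, aux_rate * excess)
    rich = Medium("rich", rich_limits)
    return {"minimal": minimal, "base": base, "rich": rich}
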
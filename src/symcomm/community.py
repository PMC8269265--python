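"""Join species models into a shared-lumen community; enumerate subsets.

Each member keeps its full network under a ``member::`` namespace.  Its
original boundary exchanges ``met_e ↔ ∅`` are rewired into species
exchanges ``member::met_e ↔ met_u`` against a shared lumen compartment
("u"), and one community exchange ``met_u ↔ ∅`` per distinct lumen
metabolite connects the lumen to the host-controlled environment.  Species
exchange bounds replicate the member's original exchange bounds (scaled by
abundance in the SteadyCom LP); community exchange bounds are fixed by the
medium and are never abundance-scaled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .model_core import Reaction, SpeciesModel

NAMESPACE_SEP = "::"

#: default cap on unconstrained community secretion (mmol·gDW⁻¹·h⁻¹)
DEFAULT_SECRETION_CAP = 1000.0


class CommunityBuildError(ValueError):
    pass


def lumen_id(env_met: str) -> str:
    """Lumen counterpart of a boundary metabolite id (glc_e → glc_u)."""
    if env_met.endswith("_e"):
        return env_met[:-2] + "_u"
    return env_met + "_u"


@dataclass
class CommunityReaction:
    """A namespaced reaction in the community network."""

    id: str
    stoich: Dict[str, float]
    lower_bound: float
    upper_bound: float
    member: Optional[str] = None       # None for community exchanges
    is_species_exchange: bool = False
    is_community_exchange: bool = False
    lumen_metabolite: Optional[str] = None
    is_biomass: bool = False


@dataclass
class CommunityModel:
    """K namespaced species joined through a shared lumen compartment."""

    id: str
    members: List[str]
    species_models: Dict[str, SpeciesModel]
    reactions: List[CommunityReaction]
    metabolite_ids: List[str]
    lumen_metabolites: List[str]
    env_metabolite_of: Dict[str, str]          # lumen met -> env met id
    biomass_reaction_of: Dict[str, str]        # member -> namespaced rxn id
    medium_name: Optional[str] = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def community_exchanges(self) -> Dict[str, CommunityReaction]:
        return {r.lumen_metabolite: r for r in self.reactions
                if r.is_community_exchange}

    def species_exchanges(self, member: str) -> List[CommunityReaction]:
        return [r for r in self.reactions
                if r.is_species_exchange and r.member == member]

    def reaction(self, rxn_id: str) -> CommunityReaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)


def build_community(models: List[SpeciesModel],
                    secretion_cap: float = DEFAULT_SECRETION_CAP,
                    community_id: Optional[str] = None) -> CommunityModel:
    """Assemble one community model from ≥1 species models."""
    if not models:
        raise CommunityBuildError("cannot build a community from 0 models")
    ids = [m.id for m in models]
    if len(set(ids)) != len(ids):
        raise CommunityBuildError(f"duplicate member ids in {ids}")
    for m in models:
        for met in m.metabolite_ids:
            if NAMESPACE_SEP in met:
                raise CommunityBuildError(
                    f"metabolite id {met!r} collides with the namespace "
                    f"separator {NAMESPACE_SEP!r}")

    members = sorted(ids)
    by_id = {m.id: m for m in models}
    reactions: List[CommunityReaction] = []
    met_ids: List[str] = []
    lumen_mets: List[str] = []
    env_of: Dict[str, str] = {}
    biomass_of: Dict[str, str] = {}

    for k in members:
        model = by_id[k]
        ns = lambda x: f"{k}{NAMESPACE_SEP}{x}"  # noqa: E731
        met_ids.extend(ns(m) for m in model.metabolite_ids)
        for r in model.reactions:
            rid = ns(r.id)
            if r.is_exchange:
                env_met = r.exchange_metabolite
                coef = r.stoich[env_met]           # -1 by convention
                lum = lumen_id(env_met)
                if lum not in env_of:
                    env_of[lum] = env_met
                    lumen_mets.append(lum)
                elif env_of[lum] != env_met:
                    raise CommunityBuildError(
                        f"lumen id collision: {lum} from both "
                        f"{env_of[lum]} and {env_met}")
                reactions.append(CommunityReaction(
                    id=rid, stoich={ns(env_met): coef, lum: -coef},
                    lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                    member=k, is_species_exchange=True,
                    lumen_metabolite=lum))
            else:
                reactions.append(CommunityReaction(
                    id=rid,
                    stoich={ns(m): c for m, c in r.stoich.items()},
                    lower_bound=r.lower_bound, upper_bound=r.upper_bound,
                    member=k,
                    is_biomass=(r.id == model.biomass_reaction_id)))
        biomass_of[k] = ns(model.biomass_reaction_id)

    for lum in lumen_mets:
        reactions.append(CommunityReaction(
            id=f"EX_{lum}", stoich={lum: -1.0},
            lower_bound=0.0, upper_bound=secretion_cap,
            member=None, is_community_exchange=True, lumen_metabolite=lum))
    met_ids.extend(lumen_mets)

    return CommunityModel(
        id=community_id or "+".join(members),
        members=members,
        species_models={k: by_id[k] for k in members},
        reactions=reactions,
        metabolite_ids=met_ids,
        lumen_metabolites=lumen_mets,
        env_metabolite_of=env_of,
        biomass_reaction_of=biomass_of)


def enumerate_subcommunities(pool: List[SpeciesModel],
                             cap: int = 10,
                             secretion_cap: float = DEFAULT_SECRETION_CAP
                             ) -> List[CommunityModel]:
    """All 2^n − 1 non-empty subsets, deterministically ordered.

    Order: by community size, then by the sorted member-id tuple.
    """
    if not pool:
        raise CommunityBuildError("empty species pool")
    if len(pool) > cap:
        raise CommunityBuildError(
            f"pool size {len(pool)} exceeds cap {cap}")
    by_id = {m.id: m for m in pool}
    ids = sorted(by_id)
    out = []
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            out.append(build_community([by_id[i] for i in combo],
                                       secretion_cap=secretion_cap))
    return out
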
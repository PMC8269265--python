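"""Ecology statistics over solved communities.

Interactions between member pairs are classified from the change in biomass
formation rate μ·X_k relative to monoculture (competitive, parasitic,
mutualistic, commensal, amensal, neutral); metabolite traffic through the
lumen is classified into use patterns (single-use, co-consumed, cross-fed,
single-produced, coproduced); and community-exchange secretion identifies
metabolites made available to the host.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

from .model_core import load_category_table, lookup_category
from .steadycom import SteadyComSolution

#: zero tolerance for growth deltas (gDW·h⁻¹) and flux sign calls (mmol·h⁻¹)
EPS = 1e-6

INTERACTION_CATEGORIES = ("competitive", "parasitic", "mutualistic",
                          "commensal", "amensal", "neutral")
USE_PATTERNS = ("single-use", "co-consumed", "cross-fed",
                "single-produced", "coproduced")


@dataclass
class InteractionRecord:
    community: FrozenSet[str]
    medium: str
    pair: Tuple[str, str]
    delta_a: float
    delta_b: float
    category: str


@dataclass
class UsePatternRecord:
    metabolite: str            # environment-facing id (e.g. glc_e)
    category: str              # metabolite class
    community: FrozenSet[str]
    medium: str
    pattern: str
    consumers: FrozenSet[str]
    producers: FrozenSet[str]


@dataclass
class HostOutputRecord:
    metabolite: str
    medium: str
    communities: List[FrozenSet[str]]
    max_net_release: float     # mmol·h⁻¹·gDW⁻¹, largest across communities


def _sign(x: float, eps: float) -> int:
    if x > eps:
        return 1
    if x < -eps:
        return -1
    return 0


def classify_interaction(delta_a: float, delta_b: float,
                         eps: float = EPS) -> str:
    """Map a pair of growth changes onto the six interaction categories.

    (−,−) competitive; one up one down parasitic; (+,+) mutualistic;
    (+,0) commensal; (−,0) amensal; (0,0) neutral.  |x| ≤ eps counts as
    zero, so the table is exhaustive and mutually exclusive.
    """
    sa, sb = _sign(delta_a, eps), _sign(delta_b, eps)
    if sa == -1 and sb == -1:
        return "competitive"
    if {sa, sb} == {1, -1}:
        return "parasitic"
    if sa == 1 and sb == 1:
        return "mutualistic"
    if {sa, sb} == {1, 0}:
        return "commensal"
    if {sa, sb} == {-1, 0}:
        return "amensal"
    return "neutral"


def classify_all_pairs(
        solutions: Mapping[FrozenSet[str], SteadyComSolution],
        monocultures: Mapping[str, SteadyComSolution],
        eps: float = EPS) -> List[InteractionRecord]:
    """One record per unordered member pair per community of size ≥ 2.

    Growth changes compare the member's biomass formation rate in the full
    community against its monoculture on the same medium.
    """
    records = []
    for members, sol in sorted(solutions.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        if len(members) < 2:
            continue
        growth = sol.growth_rates
        for a, b in itertools.combinations(sorted(members), 2):
            for m in (a, b):
                if m not in monocultures:
                    raise KeyError(f"missing monoculture solution for {m}")
            da = growth[a] - monocultures[a].growth_rates[a]
            db = growth[b] - monocultures[b].growth_rates[b]
            records.append(InteractionRecord(
                community=frozenset(members), medium=sol.medium,
                pair=(a, b), delta_a=da, delta_b=db,
                category=classify_interaction(da, db, eps)))
    return records


def classify_use_pattern(metabolite: str, consumers: Set[str],
                         producers: Set[str]) -> Optional[str]:
    """Use pattern from the consumer/producer sets (by net lumen flux).

    Returns None when the metabolite is untouched (skipped).
    """
    if not consumers and not producers:
        return None
    if not producers:
        return "single-use" if len(consumers) == 1 else "co-consumed"
    if consumers - producers:
        return "cross-fed"
    if len(producers) == 1:
        return "single-produced"
    return "coproduced"


def consumers_and_producers(solution: SteadyComSolution,
                            eps: float = EPS
                            ) -> Dict[str, Tuple[Set[str], Set[str]]]:
    """Per lumen metabolite: (consumers, producers) by net species-lumen
    flux; a member on both sides of the same metabolite is assigned by the
    net sign alone."""
    out: Dict[str, Tuple[Set[str], Set[str]]] = {
        lum: (set(), set()) for lum in solution.community.lumen_metabolites}
    for member in solution.members:
        for lum, flux in solution.species_lumen_flux(member).items():
            if flux < -eps:
                out[lum][0].add(member)
            elif flux > eps:
                out[lum][1].add(member)
    return out


def build_use_pattern_records(
        solutions: Mapping[FrozenSet[str], SteadyComSolution],
        eps: float = EPS,
        category_table: Optional[Dict[str, str]] = None
        ) -> List[UsePatternRecord]:
    if category_table is None:
        category_table = load_category_table()
    records = []
    for members, sol in sorted(solutions.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        env_of = sol.community.env_metabolite_of
        for lum, (cons, prods) in consumers_and_producers(sol, eps).items():
            pattern = classify_use_pattern(lum, cons, prods)
            if pattern is None:
                continue
            env = env_of[lum]
            records.append(UsePatternRecord(
                metabolite=env,
                category=lookup_category(env, category_table),
                community=frozenset(members), medium=sol.medium,
                pattern=pattern, consumers=frozenset(cons),
                producers=frozenset(prods)))
    return records


def use_pattern_frequencies(records: Iterable[UsePatternRecord]
                            ) -> Dict[str, Dict[str, float]]:
    """Per metabolite: relative frequency of each use pattern.

    Frequency = occurrences of the pattern / total occurrences of the
    metabolite being produced or consumed across all communities of the
    medium; frequencies per metabolite sum to 1.
    """
    counts: Dict[str, Dict[str, int]] = {}
    for rec in records:
        counts.setdefault(rec.metabolite, {p: 0 for p in USE_PATTERNS})
        counts[rec.metabolite][rec.pattern] += 1
    freqs = {}
    for met, by_pattern in counts.items():
        total = sum(by_pattern.values())
        freqs[met] = {p: c / total for p, c in by_pattern.items()}
    return freqs


def count_overlapping_inputs(solution: SteadyComSolution,
                             eps: float = EPS) -> Dict[str, int]:
    """Metabolites with ≥2 net consumers, community-wide and pairwise-max."""
    cp = consumers_and_producers(solution, eps)
    community_count = sum(1 for cons, _ in cp.values() if len(cons) >= 2)
    pairwise_max = 0
    members = solution.members
    for a, b in itertools.combinations(members, 2):
        shared = sum(1 for cons, _ in cp.values() if a in cons and b in cons)
        pairwise_max = max(pairwise_max, shared)
    return {"community_count": community_count, "pairwise_max": pairwise_max}


def metabolite_richness(solution: SteadyComSolution, taxon: str,
                        eps: float = EPS) -> Dict[str, int]:
    """Number of lumen metabolites the taxon net-consumes / net-releases."""
    if taxon not in solution.members:
        raise KeyError(f"taxon {taxon!r} not in community "
                       f"{solution.community.id}")
    fluxes = solution.species_lumen_flux(taxon)
    return {"n_consumed": sum(1 for f in fluxes.values() if f < -eps),
            "n_released": sum(1 for f in fluxes.values() if f > eps)}


def host_available_outputs(
        solutions: Mapping[FrozenSet[str], SteadyComSolution],
        eps: float = EPS) -> List[HostOutputRecord]:
    """Metabolites with net community secretion > eps in ≥1 community."""
    hits: Dict[str, List[Tuple[FrozenSet[str], float]]] = {}
    medium = None
    for members, sol in sorted(solutions.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        medium = sol.medium
        env_of = sol.community.env_metabolite_of
        for lum, flux in sol.community_secretion().items():
            if flux > eps:
                hits.setdefault(env_of[lum], []).append(
                    (frozenset(members), flux))
    return [HostOutputRecord(metabolite=met, medium=medium or "unspecified",
                             communities=[c for c, _ in lst],
                             max_net_release=max(f for _, f in lst))
            for met, lst in sorted(hits.items())]


def host_output_summary(per_medium: Mapping[str, List[HostOutputRecord]]
                        ) -> Dict[str, List[str]]:
    """Per-medium host-available metabolite lists plus their intersection."""
    out = {medium: sorted(r.metabolite for r in recs)
           for medium, recs in per_medium.items()}
    sets = [set(v) for v in out.values()]
    out["intersection"] = sorted(set.intersection(*sets)) if sets else []
    return out


def role_profile(solutions: Mapping[FrozenSet[str], SteadyComSolution],
                 taxon: str, eps: float = EPS
                 ) -> Dict[str, Dict[str, float]]:
    """Per metabolite: fraction of communities containing the taxon where it
    is a net producer / net consumer."""
    containing = [sol for members, sol in solutions.items()
                  if taxon in members]
    if not containing:
        raise KeyError(f"no solved community contains {taxon!r}")
    n = len(containing)
    prod: Dict[str, int] = {}
    cons: Dict[str, int] = {}
    mets: Set[str] = set()
    for sol in containing:
        env_of = sol.community.env_metabolite_of
        for lum, flux in sol.species_lumen_flux(taxon).items():
            env = env_of[lum]
            mets.add(env)
            if flux > eps:
                prod[env] = prod.get(env, 0) + 1
            elif flux < -eps:
                cons[env] = cons.get(env, 0) + 1
    return {met: {"producer_frequency": prod.get(met, 0) / n,
                  "consumer_frequency": cons.get(met, 0) / n}
            for met in sorted(mets)}
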
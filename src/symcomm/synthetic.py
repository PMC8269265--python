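"""Synthetic species pools, interaction scenarios and tiered media.

The generator emulates the structure the analysis assumes in real
gut-bacterial models: a carbon → biomass backbone, configurable
auxotrophies for non-substitutable metabolites (amino acids, B vitamins),
growth-coupled secretion of overflow products, and three nutrient tiers.
Stoichiometry and yields are chosen integer-ish so every reference optimum
is exactly representable and closed-form oracles stay exact.

Each of the six ecological interaction types is constructible by design:

* competition — crossed requirements for two shared limiting vitamins,
* parasitism — a secreting prototroph feeding a more efficient auxotroph
  that competes for the shared carbon source,
* mutualism — reciprocal auxotrophy with growth-coupled secretion,
* commensalism — one-way rescue on disjoint carbon sources,
* amensalism — a structurally non-growing bystander beside a displaced
  competitor,
* neutralism — disjoint, individually saturating resources.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .media import DEFAULT_PRIMARY_SOURCES, Medium, make_tiered_media, \
    save_medium
from .model_core import Metabolite, Reaction, SpeciesModel, \
    assign_categories, write_model_json

SCENARIO_NAMES = ("competition", "parasitism", "mutualism", "commensalism",
                  "amensalism", "neutralism", "five_member_demo")

#: ammonia demand per unit biomass (mmol·gDW⁻¹); ample in every tier
NH4_PER_BIOMASS = 0.5


@dataclass
class ToySpec:
    """Blueprint for a randomized pool; deterministic for a fixed seed."""

    n_species: int
    carbon_sources: List[str]
    auxotrophies: Dict[str, Dict[str, float]]     # species -> met -> coef
    secretions: Dict[str, Dict[str, float]]       # species -> met -> yield
    biomass_yield: float = 0.1
    yields: Optional[Dict[str, float]] = None     # per-species overrides
    carbons_of: Optional[Dict[str, List[str]]] = None
    seed: int = 0


@dataclass
class Scenario:
    name: str
    pool: List[SpeciesModel]
    media: Dict[str, Medium]
    target_pair: Tuple[str, str]
    target_medium: str
    expected_category: str
    description: str = ""


def make_species(species_id: str,
                 carbons: List[str],
                 biomass_yield: float,
                 auxotrophies: Optional[Dict[str, float]] = None,
                 secretions: Optional[Dict[str, float]] = None,
                 futile_cycle: bool = False) -> SpeciesModel:
    """Small species model: uptake → precursor → biomass, with auxotrophy
    requirements and growth-coupled secretions in the biomass reaction."""
    auxotrophies = auxotrophies or {}
    secretions = secretions or {}
    overlap = set(auxotrophies) & set(secretions)
    if overlap:
        raise ValueError(f"{species_id}: metabolites {sorted(overlap)} "
                         f"cannot be both required and secreted")
    if biomass_yield <= 0:
        raise ValueError(f"{species_id}: non-positive biomass yield")

    mets = [Metabolite("prec_c", "carbon precursor", "c"),
            Metabolite("nh4_e", "ammonia", "e")]
    rxns = [Reaction("EX_nh4", {"nh4_e": -1.0}, is_exchange=True)]
    biomass_stoich: Dict[str, float] = {"prec_c": -1.0 / biomass_yield,
                                        "nh4_e": -NH4_PER_BIOMASS}
    for c in carbons:
        mets.append(Metabolite(f"{c}_e", c, "e"))
        rxns.append(Reaction(f"EX_{c}", {f"{c}_e": -1.0}, is_exchange=True))
        rxns.append(Reaction(f"CNV_{c}", {f"{c}_e": -1.0, "prec_c": 1.0},
                             lower_bound=0.0))
    for a, coef in sorted(auxotrophies.items()):
        mets.append(Metabolite(f"{a}_e", a, "e"))
        rxns.append(Reaction(f"EX_{a}", {f"{a}_e": -1.0}, is_exchange=True))
        biomass_stoich[f"{a}_e"] = -float(coef)
    for m, y in sorted(secretions.items()):
        mets.append(Metabolite(f"{m}_e", m, "e"))
        rxns.append(Reaction(f"EX_{m}", {f"{m}_e": -1.0}, is_exchange=True))
        biomass_stoich[f"{m}_e"] = float(y)
    if futile_cycle:
        mets += [Metabolite("fx_c", "futile x", "c"),
                 Metabolite("fy_c", "futile y", "c")]
        rxns.append(Reaction("FUT_A", {"fx_c": -1.0, "fy_c": 1.0},
                             lower_bound=0.0))
        rxns.append(Reaction("FUT_B", {"fy_c": -1.0, "fx_c": 1.0},
                             lower_bound=0.0))
    rxns.append(Reaction("BIOMASS", biomass_stoich, lower_bound=0.0))
    model = SpeciesModel(id=species_id, metabolites=mets, reactions=rxns,
                         biomass_reaction_id="BIOMASS")
    return assign_categories(model)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def _tiers(minimal_limits: Dict[str, float],
           base_extras: Dict[str, float],
           excess: float = 10.0) -> Dict[str, Medium]:
    """Three-tier media with limits an order of magnitude apart."""
    minimal = dict(DEFAULT_PRIMARY_SOURCES)
    minimal.update(minimal_limits)
    base = dict(minimal)
    base.update(base_extras)
    rich = {m: v * excess for m, v in base.items()}
    return {"minimal": Medium("minimal", minimal),
            "base": Medium("base", base),
            "rich": Medium("rich", rich)}


def make_scenario(name: str) -> Scenario:
    """Pool + three-tier media engineered so the canonical pipeline
    classifies the named interaction for the designated pair/medium."""
    if name == "competition":
        # crossed demands on two shared vitamins: v1+2·v2 (CA), 2·v1+v2 (CB)
        # each at 3 mmol → monoculture μ = 1.5, coculture rates 1.0 each
        pool = [make_species("CA", ["glc"], 0.1, {"v1": 1.0, "v2": 2.0}),
                make_species("CB", ["glyc"], 0.1, {"v1": 2.0, "v2": 1.0})]
        media = _tiers({"glc_e": 1000.0, "glyc_e": 1000.0,
                        "v1_e": 3.0, "v2_e": 3.0}, {})
        return Scenario(name, pool, media, ("CA", "CB"), "minimal",
                        "competitive",
                        "both depressed by shared vitamin limitation")
    if name == "parasitism":
        # PA secretes the growth factor PB needs; PB outcompetes PA for
        # glucose: PA 1.0 → 0.5, PB 0 → 1.0 on minimal
        pool = [make_species("PA", ["glc"], 0.1, secretions={"paux": 2.0}),
                make_species("PB", ["glc"], 0.2, {"paux": 1.0})]
        media = _tiers({"glc_e": 10.0, "glyc_e": 0.0}, {"paux_e": 10.0})
        return Scenario(name, pool, media, ("PA", "PB"), "minimal",
                        "parasitic", "one-way rescue at the host's expense")
    if name == "mutualism":
        # reciprocal auxotrophy: neither grows alone on minimal, both in
        # coculture (0 → 0.5 and 0 → 1.0)
        pool = [make_species("MA", ["glc"], 0.1, {"mb": 1.0}, {"ma": 2.0}),
                make_species("MB", ["glc"], 0.2, {"ma": 1.0}, {"mb": 2.0})]
        media = _tiers({"glc_e": 10.0, "glyc_e": 0.0},
                       {"ma_e": 10.0, "mb_e": 10.0})
        return Scenario(name, pool, media, ("MA", "MB"), "minimal",
                        "mutualistic", "reciprocal cross-feeding rescue")
    if name == "commensalism":
        # NA feeds NB on a disjoint carbon source: NA 1.0 → 1.0 (unchanged),
        # NB 0 → 2.0
        pool = [make_species("NA", ["glc"], 0.1, secretions={"cm": 2.0}),
                make_species("NB", ["glyc"], 0.2, {"cm": 1.0})]
        media = _tiers({"glc_e": 10.0, "glyc_e": 10.0}, {"cm_e": 10.0})
        return Scenario(name, pool, media, ("NA", "NB"), "minimal",
                        "commensal", "one-way rescue without competition")
    if name == "amensalism":
        # AB cannot grow on minimal (missing vitamin, no producer) and so
        # stays at exactly zero, while the superior competitor AC displaces
        # AA from the shared glucose: pair (AA, AB) is (−, 0)
        pool = [make_species("AA", ["glc"], 0.1),
                make_species("AB", ["glc"], 0.2, {"va": 1.0}),
                make_species("AC", ["glc"], 0.12)]
        media = _tiers({"glc_e": 10.0, "glyc_e": 0.0}, {"va_e": 10.0})
        return Scenario(name, pool, media, ("AA", "AB"), "minimal",
                        "amensal",
                        "third-party competition beside a structural zero")
    if name == "neutralism":
        # disjoint saturating resources: 1.0 → 1.0 and 2.0 → 2.0
        pool = [make_species("UA", ["glc"], 0.1),
                make_species("UB", ["glyc"], 0.2)]
        media = _tiers({"glc_e": 10.0, "glyc_e": 10.0}, {})
        return Scenario(name, pool, media, ("UA", "UB"), "minimal",
                        "neutral", "no shared constraint")
    if name == "five_member_demo":
        pool = five_member_pool()
        media = make_tiered_media(pool)
        return Scenario(name, pool, media, ("AF", "AP"), "minimal",
                        "parasitic",
                        "five-taxon pool with auxotrophy rescue structure")
    raise ValueError(f"unknown scenario {name!r}; "
                     f"choose from {SCENARIO_NAMES}")


def five_member_pool() -> List[SpeciesModel]:
    """Five taxa echoing the AAB/LAB structure of a fly-gut community:
    two prototrophic producers (AP, AT), an arginine auxotroph (AF), and
    two lactobacilli (LP with an arginine requirement and cell-wall
    precursor secretion, LB requiring both arginine and that precursor)."""
    return [
        make_species("AP", ["glc"], 0.10,
                     secretions={"arg": 2.0, "ac": 1.0}),
        make_species("AT", ["glc"], 0.12,
                     secretions={"arg": 1.0, "thm": 1.0}),
        make_species("AF", ["glc"], 0.15, {"arg": 1.0},
                     secretions={"ac": 2.0}),
        make_species("LP", ["glc", "glyc"], 0.20, {"arg": 1.0},
                     secretions={"dap": 2.0, "lac": 1.0}),
        make_species("LB", ["glc", "glyc"], 0.25,
                     {"arg": 1.0, "dap": 1.0},
                     secretions={"succ": 1.0}),
    ]


# ---------------------------------------------------------------------------
# Random pools with planted wiring
# ---------------------------------------------------------------------------

_AUX_CANDIDATES = ("thm", "btn", "ribflv", "arg", "dap")
_OVERFLOW = ("ac", "lac", "succ", "akg")
_YIELD_GRID = (0.05, 0.1, 0.15, 0.2, 0.25)


def make_random_spec(n_species: int = 5, seed: int = 0,
                     p_auxotroph: float = 0.6) -> ToySpec:
    """Random auxotrophy/secretion wiring; every required metabolite is
    secreted by at least one prototroph so pools stay rescuable."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i}" for i in range(n_species)]
    carbons_of, aux, sec, yields = {}, {}, {}, {}
    prototrophs = ids[:max(1, n_species // 2)]
    secreted: List[str] = []
    for sid in ids:
        carbons_of[sid] = [str(rng.choice(["glc", "glyc"]))]
        yields[sid] = float(rng.choice(_YIELD_GRID))
        aux[sid] = {}
        sec[sid] = {}
        if sid in prototrophs:
            for met in rng.choice(_AUX_CANDIDATES,
                                  size=rng.integers(1, 3), replace=False):
                sec[sid][str(met)] = float(rng.integers(1, 3))
                secreted.append(str(met))
            sec[sid][str(rng.choice(_OVERFLOW))] = 1.0
        elif rng.random() < p_auxotroph and secreted:
            met = str(rng.choice(sorted(set(secreted))))
            aux[sid][met] = 1.0
            overflow = str(rng.choice(_OVERFLOW))
            sec[sid][overflow] = 1.0
    return ToySpec(n_species=n_species,
                   carbon_sources=["glc", "glyc"],
                   auxotrophies=aux, secretions=sec,
                   yields=yields, carbons_of=carbons_of, seed=seed)


def make_random_pool(spec: ToySpec
                     ) -> Tuple[List[SpeciesModel], Dict[str, object]]:
    """Materialize a ToySpec; returns (pool, ground-truth wiring table)."""
    pool = []
    for sid in sorted(spec.auxotrophies):
        pool.append(make_species(
            sid,
            (spec.carbons_of or {}).get(sid, [spec.carbon_sources[0]]),
            (spec.yields or {}).get(sid, spec.biomass_yield),
            spec.auxotrophies[sid], spec.secretions.get(sid, {})))
    edges = [(a, met, b)
             for a in spec.secretions for met in spec.secretions[a]
             for b in spec.auxotrophies if met in spec.auxotrophies[b]]
    truth = {"seed": spec.seed,
             "auxotrophies": {k: sorted(v) for k, v in
                              spec.auxotrophies.items()},
             "secretions": {k: dict(v) for k, v in spec.secretions.items()},
             "cross_feeding_edges": sorted(edges)}
    return pool, truth


def write_pool(pool: List[SpeciesModel], media: Dict[str, Medium],
               outdir, truth: Optional[dict] = None) -> Path:
    """Write a pool as JSON-dialect models + medium TSVs (+ ground truth)."""
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    (outdir / "media").mkdir(exist_ok=True)
    manifest = {"members": [m.id for m in pool],
                "model_paths": {m.id: f"models/{m.id}.json" for m in pool}}
    for m in pool:
        write_model_json(m, outdir / "models" / f"{m.id}.json")
    for tier, medium in media.items():
        save_medium(medium, outdir / "media" / f"{tier}.tsv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    if truth is not None:
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return outdir
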
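"""Orchestrate the full experiment: all subcommunities × all media.

For every community × medium cell the canonical solve chain is
max-growth → FVA → medoid floors → constrained re-solve → L1 flux
minimization; ecology statistics are then derived per medium and written
as TSV/JSON reports with a provenance manifest.  Cells are independent,
cached by config hash, and re-runs skip completed cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional

import pandas as pd

from . import __version__
from .community import CommunityModel, build_community, \
    enumerate_subcommunities
from .ecology import EPS, build_use_pattern_records, classify_all_pairs, \
    count_overlapping_inputs, host_available_outputs, host_output_summary, \
    metabolite_richness, use_pattern_frequencies
from .media import Medium, apply_medium, load_medium
from .model_core import SpeciesModel, read_model_json
from .steadycom import MU_TOL, SteadyComProblem, SteadyComSolution, \
    compute_medoid, l1_minimize, solve_constrained, steadycom_fva, \
    steadycom_max_growth
from .synthetic import SCENARIO_NAMES, make_scenario

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.9f"


@dataclass
class RunConfig:
    """Validated configuration for one experiment run."""

    out: str
    scenario: Optional[str] = None        # synthetic scenario name, or …
    manifest: Optional[str] = None        # … model manifest JSON
    media_dir: Optional[str] = None
    fva_fraction: float = 0.9999
    eps: float = EPS
    mu_tol: float = MU_TOL
    fva_max_reactions: Optional[int] = None
    subcommunity_cap: int = 10
    medoid_mode: str = "growth_rate"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fva_fraction <= 1:
            raise ValueError("fva_fraction must be in (0, 1]")
        if self.scenario is None and self.manifest is None:
            raise ValueError("provide either a scenario or a model manifest")
        if self.scenario is not None and self.scenario not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.manifest is not None and self.media_dir is None:
            raise ValueError("a model manifest requires --media")


def load_inputs(config: RunConfig):
    if config.scenario is not None:
        sc = make_scenario(config.scenario)
        return sc.pool, sc.media
    with open(config.manifest) as fh:
        manifest = json.load(fh)
    root = Path(config.manifest).parent
    pool = [read_model_json(root / manifest["model_paths"][mid])
            for mid in manifest["members"]]
    media = {}
    for path in sorted(Path(config.media_dir).glob("*.tsv")):
        media[path.stem] = load_medium(path, name=path.stem)
    if not media:
        raise ValueError(f"no .tsv media found in {config.media_dir}")
    return pool, media


def _config_hash(config: RunConfig, pool: List[SpeciesModel],
                 media: Mapping[str, Medium]) -> str:
    h = hashlib.sha256()
    payload = {k: v for k, v in asdict(config).items() if k != "out"}
    payload["version"] = __version__
    payload["pool"] = [[m.id, sorted(m.metabolite_ids),
                        [[r.id, sorted(r.stoich.items()), r.lower_bound,
                          r.upper_bound, r.is_exchange]
                         for r in m.reactions], m.biomass_reaction_id]
                       for m in pool]
    payload["media"] = {name: [sorted(md.uptake_limits.items()),
                               sorted(md.secretion_limits.items())]
                        for name, md in media.items()}
    h.update(json.dumps(payload, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def solve_cell(community: CommunityModel, medium: Medium,
               config: RunConfig) -> SteadyComSolution:
    """Canonical solve chain for one community × medium cell."""
    apply_medium(community, medium)
    prob = SteadyComProblem(community)
    sol = steadycom_max_growth(community, mu_tol=config.mu_tol,
                               problem=prob)
    if sol.mu <= 0:
        return sol
    scan = None
    if config.fva_max_reactions is not None:
        scan = [r.id for r in community.reactions][:config.fva_max_reactions]
    report = steadycom_fva(community, solution=sol,
                           fraction=config.fva_fraction,
                           reactions=scan, problem=prob)
    medoid = compute_medoid(report, mode=config.medoid_mode)
    sol = solve_constrained(community, medoid, mu_tol=config.mu_tol,
                            problem=prob)
    sol = l1_minimize(community, sol, problem=prob)
    sol.notes["fva_ranges"] = {
        rid: rng for rid, rng in report.ranges.items()}
    return sol


# -- cell cache -------------------------------------------------------------

def _cell_path(outdir: Path, medium: str, community: CommunityModel) -> Path:
    return outdir / "cells" / f"{medium}__{community.id.replace('+', '-')}.json"


def _save_cell(path: Path, sol: SteadyComSolution, run_hash: str) -> None:
    notes = {k: v for k, v in sol.notes.items() if k != "fva_ranges"}
    doc = {"hash": run_hash, "mu": sol.mu, "X": sol.X, "V": sol.V,
           "status": sol.status, "medium": sol.medium, "notes": notes,
           "fva_ranges": sol.notes.get("fva_ranges")}
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def _load_cell(path: Path, community: CommunityModel, medium: Medium,
               run_hash: str) -> Optional[SteadyComSolution]:
    if not path.exists():
        return None
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("hash") != run_hash:
        return None
    apply_medium(community, medium)
    notes = dict(doc.get("notes") or {})
    if doc.get("fva_ranges") is not None:
        notes["fva_ranges"] = doc["fva_ranges"]
    notes["cached"] = True
    return SteadyComSolution(community=community, medium=doc["medium"],
                             mu=doc["mu"], X=doc["X"], V=doc["V"],
                             status=doc["status"], notes=notes)


# -- reports ----------------------------------------------------------------

def _community_label(members: FrozenSet[str]) -> str:
    return "+".join(sorted(members))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_reports(outdir: Path,
                  solutions: Dict[str, Dict[FrozenSet[str],
                                            SteadyComSolution]],
                  config: RunConfig) -> None:
    sol_rows, flux_rows, inter_rows, pattern_rows = [], [], [], []
    freq_rows, overlap_rows, rich_rows, host_rows = [], [], [], []
    summary: Dict[str, dict] = {}
    for medium in sorted(solutions):
        sols = solutions[medium]
        for members in sorted(sols, key=lambda s: (len(s), sorted(s))):
            sol = sols[members]
            label = _community_label(members)
            for k in sol.members:
                sol_rows.append({
                    "community": label, "medium": medium,
                    "size": len(members), "member": k, "X": sol.X[k],
                    "growth_rate_gdw_h": sol.growth_rates[k],
                    "status": sol.status})
            ranges = sol.notes.get("fva_ranges") or {}
            for rid in sorted(sol.V):
                rng = ranges.get(rid)
                flux_rows.append({
                    "community": label, "medium": medium, "reaction": rid,
                    "min": rng[0] if rng else float("nan"),
                    "max": rng[1] if rng else float("nan"),
                    "value": sol.V[rid]})
            oc = count_overlapping_inputs(sol, eps=config.eps)
            overlap_rows.append({"community": label, "medium": medium,
                                 "size": len(members), **oc})
            for k in sol.members:
                rich = metabolite_richness(sol, k, eps=config.eps)
                rich_rows.append({"community": label, "medium": medium,
                                  "size": len(members), "taxon": k, **rich})
        monocultures = {next(iter(m)): s for m, s in sols.items()
                        if len(m) == 1}
        interactions = classify_all_pairs(sols, monocultures,
                                          eps=config.eps)
        for rec in interactions:
            inter_rows.append({
                "community": _community_label(rec.community),
                "medium": medium, "member_a": rec.pair[0],
                "member_b": rec.pair[1], "delta_a": rec.delta_a,
                "delta_b": rec.delta_b, "category": rec.category})
        patterns = build_use_pattern_records(sols, eps=config.eps)
        for rec in patterns:
            pattern_rows.append({
                "community": _community_label(rec.community),
                "medium": medium, "metabolite": rec.metabolite,
                "class": rec.category, "pattern": rec.pattern,
                "consumers": "+".join(sorted(rec.consumers)),
                "producers": "+".join(sorted(rec.producers))})
        for met, by_pattern in sorted(
                use_pattern_frequencies(patterns).items()):
            for pattern, freq in sorted(by_pattern.items()):
                freq_rows.append({"medium": medium, "metabolite": met,
                                  "pattern": pattern, "frequency": freq})
        host = host_available_outputs(sols, eps=config.eps)
        for rec in host:
            host_rows.append({"medium": medium, "metabolite": rec.metabolite,
                              "n_communities": len(rec.communities),
                              "max_net_release": rec.max_net_release})
        by_size: Dict[int, Dict[str, int]] = {}
        for rec in interactions:
            d = by_size.setdefault(len(rec.community), {})
            d[rec.category] = d.get(rec.category, 0) + 1
        summary[medium] = {
            "n_communities": len(sols),
            "interaction_counts_by_size": {
                str(size): {cat: n / sum(d.values()) for cat, n in
                            sorted(d.items())}
                for size, d in sorted(by_size.items())},
            "host_available": sorted(r.metabolite for r in host),
        }
    summary["host_output_summary"] = host_output_summary(
        {m: host_available_outputs(solutions[m], eps=config.eps)
         for m in sorted(solutions)})
    _write_tsv(pd.DataFrame(sol_rows), outdir / "solutions.tsv")
    _write_tsv(pd.DataFrame(flux_rows), outdir / "fluxes.tsv")
    _write_tsv(pd.DataFrame(inter_rows), outdir / "interactions.tsv")
    _write_tsv(pd.DataFrame(pattern_rows), outdir / "use_patterns.tsv")
    _write_tsv(pd.DataFrame(freq_rows), outdir / "use_pattern_frequencies.tsv")
    _write_tsv(pd.DataFrame(overlap_rows), outdir / "overlapping_inputs.tsv")
    _write_tsv(pd.DataFrame(rich_rows), outdir / "richness.tsv")
    _write_tsv(pd.DataFrame(host_rows), outdir / "host_outputs.tsv")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)


def load_solutions(config: RunConfig
                   ) -> Dict[str, Dict[FrozenSet[str], SteadyComSolution]]:
    """Reload the cached cell solutions of a completed run."""
    outdir = Path(config.out)
    pool, media = load_inputs(config)
    run_hash = _config_hash(config, pool, media)
    by_id = {m.id: m for m in pool}
    member_sets = [tuple(c.members) for c in enumerate_subcommunities(
        pool, cap=config.subcommunity_cap)]
    out: Dict[str, Dict[FrozenSet[str], SteadyComSolution]] = {}
    for medium_name in sorted(media):
        out[medium_name] = {}
        for members in member_sets:
            community = build_community([by_id[k] for k in members])
            sol = _load_cell(_cell_path(outdir, medium_name, community),
                             community, media[medium_name], run_hash)
            if sol is not None:
                out[medium_name][frozenset(members)] = sol
    return out


def run_experiment(config: RunConfig) -> Path:
    """Solve every community × medium cell and write all reports.

    Returns the run directory.  Cells failing even after medoid relaxation
    are recorded in the manifest and the run continues.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    pool, media = load_inputs(config)
    run_hash = _config_hash(config, pool, media)
    by_id = {m.id: m for m in pool}
    member_sets = [tuple(c.members) for c in enumerate_subcommunities(
        pool, cap=config.subcommunity_cap)]

    solutions: Dict[str, Dict[FrozenSet[str], SteadyComSolution]] = {}
    manifest_cells = []
    for medium_name in sorted(media):
        medium = media[medium_name]
        solutions[medium_name] = {}
        for members in member_sets:
            community = build_community([by_id[k] for k in members])
            path = _cell_path(outdir, medium_name, community)
            sol = _load_cell(path, community, medium, run_hash)
            cached = sol is not None
            status = "ok"
            if sol is None:
                try:
                    sol = solve_cell(community, medium, config)
                    _save_cell(path, sol, run_hash)
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    logger.exception("cell %s/%s failed", medium_name,
                                     community.id)
                    status = f"failed: {exc}"
                    sol = None
            if sol is not None:
                solutions[medium_name][frozenset(members)] = sol
                if sol.notes.get("medoid_dropped"):
                    status = "medoid_dropped"
            manifest_cells.append({
                "community": community.id, "medium": medium_name,
                "status": status, "cached": cached,
                "mu": sol.mu if sol else None})
    write_reports(outdir, solutions, config)
    import scipy
    manifest = {"config": {k: v for k, v in asdict(config).items()},
                "hash": run_hash, "version": __version__,
                "solver": f"scipy-{scipy.__version__}/highs",
                "seed": config.seed, "cells": manifest_cells}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir
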
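"""Shared fixtures: scenario solves and the full five-member demo run."""

from __future__ import annotations

import pytest

import symcomm as sc
from symcomm.pipeline import RunConfig, load_solutions, run_experiment, \
    solve_cell


@pytest.fixture(scope="session")
def glc_medium():
    return sc.Medium("glc10", {"glc_e": 10.0, "nh4_e": 1000.0})


def solve_scenario(name: str):
    """Full canonical chain for a scenario on its designated medium:
    monoculture solutions plus the all-member coculture."""
    scn = sc.make_scenario(name)
    medium = scn.media[scn.target_medium]
    cfg = RunConfig(out="unused", scenario=name)
    monos = {}
    for model in scn.pool:
        community = sc.build_community([model])
        monos[model.id] = solve_cell(community, medium, cfg)
    coculture = solve_cell(sc.build_community(scn.pool), medium, cfg)
    return scn, monos, coculture


@pytest.fixture(scope="session")
def scenario_solutions():
    names = ("competition", "parasitism", "mutualism", "commensalism",
             "amensalism", "neutralism")
    return {name: solve_scenario(name) for name in names}


@pytest.fixture(scope="session")
def demo_config(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo_run")
    return RunConfig(out=str(out), scenario="five_member_demo", seed=1)


@pytest.fixture(scope="session")
def demo_run(demo_config):
    """Run the full 31-community × 3-media experiment once per session."""
    return run_experiment(demo_config)


@pytest.fixture(scope="session")
def demo_solutions(demo_run, demo_config):
    return load_solutions(demo_config)
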
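"""SteadyCom LP, bisection, FVA, medoid and L1 minimization."""

import numpy as np
import pytest

import symcomm as sc
from symcomm.steadycom import (FVAReport, MedoidConstraint,
                               SteadyComError,
                               SteadyComProblem, compute_medoid,
                               l1_minimize, solve_constrained,
                               steadycom_fva, steadycom_lp,
                               steadycom_max_growth)


def mutualist_pair():
    """Reciprocal auxotrophs: closed-form coculture μ = 1.5,
    X = (1/3, 2/3) on glucose 10 (yields 0.1/0.2, secretion 2/unit)."""
    return [sc.make_species("MA", ["glc"], 0.1, {"mb": 1.0}, {"ma": 2.0}),
            sc.make_species("MB", ["glc"], 0.2, {"ma": 1.0}, {"mb": 2.0})]


class TestFixedMuLP:
    def test_chain_feasible_below_yield_bound(self, glc_medium):
        """Yield 0.1 gDW/mmol × uptake 10 → feasible iff μ ≤ 1."""
        com = sc.build_community([sc.make_species("A", ["glc"], 0.1)])
        sc.apply_medium(com, glc_medium)
        assert steadycom_lp(com, 0.999)["feasible"]
        assert not steadycom_lp(com, 1.001)["feasible"]

    def test_rescaled_onto_unit_biomass(self, glc_medium):
        com = sc.build_community([sc.make_species("A", ["glc"], 0.1)])
        sc.apply_medium(com, glc_medium)
        res = steadycom_lp(com, 0.5)
        assert sum(res["X"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_obligate_mutualists_feasible_together(self, glc_medium):
        com = sc.build_community(mutualist_pair())
        sc.apply_medium(com, glc_medium)
        res = steadycom_lp(com, 1.0)
        assert res["feasible"]
        assert min(res["X"].values()) > 0

    def test_severed_cross_feeding_collapses_pair(self, glc_medium):
        """Deleting MB's secretion of MA's requirement forces X → 0."""
        ma, mb = mutualist_pair()
        biomass = mb.reaction("BIOMASS")
        del biomass.stoich["mb_e"]  # MB no longer exports MA's requirement
        com = sc.build_community([ma, mb])
        sc.apply_medium(com, glc_medium)
        assert not steadycom_lp(com, 0.01)["feasible"]


class TestMaxGrowth:
    def test_singleton_equals_fba(self, glc_medium):
        model = sc.make_species("A", ["glc"], 0.1)
        com = sc.build_community([model])
        sc.apply_medium(com, glc_medium)
        sol = steadycom_max_growth(com)
        assert sol.mu == pytest.approx(
            sc.fba(model, glc_medium).objective, abs=1e-6)

    def test_identical_competitors_keep_monoculture_mu(self, glc_medium):
        a = sc.make_species("A", ["glc"], 0.1)
        b = sc.make_species("B", ["glc"], 0.1)
        com = sc.build_community([a, b])
        sc.apply_medium(com, glc_medium)
        sol = steadycom_max_growth(com)
        assert sol.mu == pytest.approx(1.0, abs=1e-6)
        assert sum(sol.X.values()) == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_mutualists_match_closed_form(self, glc_medium):
        """Hand-solved 2×2 system: μ = 1.5, X = (1/3, 2/3)."""
        com = sc.build_community(mutualist_pair())
        sc.apply_medium(com, glc_medium)
        sol = steadycom_max_growth(com)
        assert sol.mu == pytest.approx(1.5, abs=1e-6)
        assert sol.X["MA"] == pytest.approx(1 / 3, abs=1e-5)
        assert sol.X["MB"] == pytest.approx(2 / 3, abs=1e-5)

    def test_no_growth_returns_zero_solution(self):
        com = sc.build_community([sc.make_species("A", ["glc"], 0.1)])
        sc.apply_medium(com, sc.Medium("empty", {"nh4_e": 1000.0}))
        sol = steadycom_max_growth(com)
        assert sol.status == "no_growth"
        assert sol.mu == 0.0
        assert all(v == 0.0 for v in sol.V.values())

    def test_bisection_matches_dense_grid_oracle(self, glc_medium):
        """Grid walk at step 1e-4 agrees with bisection within one step."""
        com = sc.build_community([sc.make_species("A", ["glc"], 0.02)])
        sc.apply_medium(com, sc.Medium("m", {"glc_e": 5.0, "nh4_e": 50.0}))
        sol = steadycom_max_growth(com)
        prob = SteadyComProblem(com)
        step, mu = 1e-4, 0.0
        while True:
            res = prob.solve(mu + step, objective="max_total")
            if res["status"] != "optimal" or res["total"] < 1.0 - 1e-8:
                break
            mu += step
        assert abs(sol.mu - mu) <= step + 1e-9

    def test_lumen_balance_invariant(self, glc_medium):
        com = sc.build_community(mutualist_pair())
        sc.apply_medium(com, glc_medium)
        sol = steadycom_max_growth(com)
        assert max(abs(v) for v in sol.lumen_residuals().values()) < 1e-7

    def test_biomass_coupling_invariant(self, glc_medium):
        com = sc.build_community(mutualist_pair())
        sc.apply_medium(com, glc_medium)
        sol = steadycom_max_growth(com)
        for k in sol.members:
            assert sol.V[com.biomass_reaction_of[k]] == pytest.approx(
                sol.mu * sol.X[k], abs=1e-6)


class TestFVA:
    def test_blocked_reaction_has_zero_range(self, glc_medium):
        model = sc.make_species("A", ["glc"], 0.1, futile_cycle=True)
        model.reaction("FUT_A").upper_bound = 0.0
        model.reaction("FUT_B").upper_bound = 0.0
        com = sc.build_community([model])
        sc.apply_medium(com, glc_medium)
        report = steadycom_fva(com)
        assert report.ranges["A::FUT_A"] == pytest.approx((0.0, 0.0),
                                                          abs=1e-9)

    def test_parallel_pathways_have_width_shared_steps_fixed(self):
        """Two substitutable carbons with slack supply: either conversion
        can carry the flux (positive range width) while biomass is pinned
        by a vitamin cap."""
        model = sc.make_species("A", ["glc", "glyc"], 0.1, {"v": 1.0})
        com = sc.build_community([model])
        sc.apply_medium(com, sc.Medium("m", {"glc_e": 10.0, "glyc_e": 10.0,
                                             "v_e": 0.5, "nh4_e": 1000.0}))
        report = steadycom_fva(com, fraction=1.0 - 1e-9)
        lo, hi = report.ranges["A::CNV_glc"]
        assert hi - lo > 1.0
        blo, bhi = report.ranges["A::BIOMASS"]
        assert bhi - blo < 1e-5

    def test_growth_vector_count_is_twice_reactions(self, glc_medium):
        com = sc.build_community(mutualist_pair())
        sc.apply_medium(com, glc_medium)
        report = steadycom_fva(com)
        n_scanned = len(report.ranges)
        assert len(report.growth_vectors) == 2 * n_scanned
        assert all(len(v) == 2 for v in report.growth_vectors)

    def test_fva_requires_growth(self):
        com = sc.build_community([sc.make_species("A", ["glc"], 0.1)])
        sc.apply_medium(com, sc.Medium("empty", {}))
        with pytest.raises(SteadyComError, match="positive growth"):
            steadycom_fva(com)


class TestMedoid:
    def test_brute_force_oracle(self):
        """Medoid of {(1,2),(1,2),(5,6)} is (1,2): verified by explicit
        pairwise distance sums."""
        vectors = [np.array(v) for v in [(1.0, 2.0), (1.0, 2.0),
                                         (5.0, 6.0)]]
        report = FVAReport(members=["A", "B"], ranges={},
                           growth_vectors=vectors, mu=1.0)
        best, best_sum = None, np.inf
        for v in vectors:
            s = sum(np.linalg.norm(v - w) for w in vectors)
            if s < best_sum:
                best, best_sum = v, s
        med = compute_medoid(report)
        assert med.bounds == {"A": best[0], "B": best[1]} == \
            {"A": 1.0, "B": 2.0}

    def test_single_vector_is_its_own_medoid(self):
        report = FVAReport(members=["A"], ranges={},
                           growth_vectors=[np.array([0.7])], mu=1.0)
        assert compute_medoid(report).bounds == {"A": 0.7}

    def test_ties_break_on_first_occurrence(self):
        vectors = [np.array([2.0]), np.array([1.0]), np.array([1.0]),
                   np.array([2.0])]
        report = FVAReport(members=["A"], ranges={},
                           growth_vectors=vectors, mu=1.0)
        # all distance sums equal (1+1 each side): first vector wins
        assert compute_medoid(report).bounds == {"A": 2.0}

    def test_empty_report_is_error(self):
        report = FVAReport(members=["A"], ranges={}, growth_vectors=[],
                           mu=1.0)
        with pytest.raises(ValueError, match="empty"):
            compute_medoid(report)

    def test_abundance_mode_divides_by_mu(self):
        report = FVAReport(members=["A"], ranges={},
                           growth_vectors=[np.array([0.5])], mu=2.0)
        med = compute_medoid(report, mode="abundance")
        assert med.bounds == {"A": 0.25}


class TestConstrainedSolve:
    def test_zero_floors_reproduce_unconstrained(self, glc_medium):
        com = sc.build_community(mutualist_pair())
        sc.apply_medium(com, glc_medium)
        free = steadycom_max_growth(com)
        sol = solve_constrained(com, MedoidConstraint({"MA": 0.0,
                                                       "MB": 0.0}))
        assert sol.mu == pytest.approx(free.mu, abs=1e-6)

    def test_floors_hold_in_final_solution(self, glc_medium):
        com = sc.build_community(mutualist_pair())
        sc.apply_medium(com, glc_medium)
        report = steadycom_fva(com)
        medoid = compute_medoid(report)
        sol = solve_constrained(com, medoid)
        for k, floor in medoid.bounds.items():
            assert sol.growth_rates[k] >= floor - 1e-6

    def test_singleton_mu_unchanged_by_medoid(self, glc_medium):
        com = sc.build_community([sc.make_species("A", ["glc"], 0.1)])
        sc.apply_medium(com, glc_medium)
        free = steadycom_max_growth(com)
        sol = solve_constrained(com, compute_medoid(steadycom_fva(com)))
        assert sol.mu == pytest.approx(free.mu, rel=1e-3)

    def test_unattainable_floor_is_relaxed_not_fatal(self, glc_medium):
        com = sc.build_community([sc.make_species("A", ["glc"], 0.1)])
        sc.apply_medium(com, glc_medium)
        # monoculture can reach at most 1.0 gDW/h; demand 2.0
        sol = solve_constrained(com, MedoidConstraint({"A": 2.0},
                                                      mu_seed=1.0))
        assert sol.mu > 0
        assert sol.notes.get("medoid_relaxations", 0) > 0 or \
            sol.notes.get("medoid_dropped")


class TestL1:
    def _loop_community(self, glc_medium):
        model = sc.make_species("A", ["glc"], 0.1, futile_cycle=True)
        com = sc.build_community([model])
        sc.apply_medium(com, glc_medium)
        return com

    def test_planted_futile_cycle_removed_mu_preserved(self, glc_medium):
        com = self._loop_community(glc_medium)
        sol = steadycom_max_growth(com)
        # plant circulating flux on the loop: still feasible, same μ
        inflated = sc.SteadyComSolution(
            community=com, medium=sol.medium, mu=sol.mu, X=dict(sol.X),
            V={**sol.V, "A::FUT_A": sol.V["A::FUT_A"] + 50.0,
               "A::FUT_B": sol.V["A::FUT_B"] + 50.0},
            status="optimal")
        assert max(abs(v) for v in inflated.lumen_residuals().values()) \
            < 1e-9
        clean = l1_minimize(com, inflated)
        assert clean.V["A::FUT_A"] == pytest.approx(0.0, abs=1e-9)
        assert clean.V["A::FUT_B"] == pytest.approx(0.0, abs=1e-9)
        assert clean.mu == sol.mu
        assert clean.growth_rates == pytest.approx(sol.growth_rates,
                                                   abs=1e-9)

    def test_idempotent_on_minimal_solution(self, glc_medium):
        com = self._loop_community(glc_medium)
        sol = steadycom_max_growth(com)
        once = l1_minimize(com, sol)
        twice = l1_minimize(com, once)
        for rid, v in once.V.items():
            assert twice.V[rid] == pytest.approx(v, abs=1e-9)

    def test_never_increases_total_flux(self, glc_medium):
        com = self._loop_community(glc_medium)
        sol = steadycom_max_growth(com)
        inflated = sc.SteadyComSolution(
            community=com, medium=sol.medium, mu=sol.mu, X=dict(sol.X),
            V={**sol.V, "A::FUT_A": sol.V["A::FUT_A"] + 7.0,
               "A::FUT_B": sol.V["A::FUT_B"] + 7.0},
            status="optimal")
        clean = l1_minimize(com, inflated)
        assert sum(abs(v) for v in clean.V.values()) <= \
            sum(abs(v) for v in inflated.V.values()) + 1e-9
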
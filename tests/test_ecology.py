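"""Interaction classification, use patterns, richness and host outputs."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

import symcomm as sc
from symcomm.ecology import (classify_interaction, classify_use_pattern,
                             consumers_and_producers,
                             count_overlapping_inputs, host_output_summary,
                             use_pattern_frequencies, INTERACTION_CATEGORIES,
                             USE_PATTERNS, UsePatternRecord)


class TestInteractionTruthTable:
    TABLE = {
        (-1, -1): "competitive",
        (1, -1): "parasitic", (-1, 1): "parasitic",
        (1, 1): "mutualistic",
        (1, 0): "commensal", (0, 1): "commensal",
        (-1, 0): "amensal", (0, -1): "amensal",
        (0, 0): "neutral",
    }

    @pytest.mark.parametrize("sa,sb", list(itertools.product((-1, 0, 1),
                                                             repeat=2)))
    def test_all_nine_sign_pairs(self, sa, sb):
        """Exhaustive: every sign combination maps to exactly one of the
        six categories, as defined (i)-(vi)."""
        delta = {1: 0.3, 0: 0.0, -1: -0.2}
        cat = classify_interaction(delta[sa], delta[sb])
        assert cat == self.TABLE[(sa, sb)]
        assert cat in INTERACTION_CATEGORIES

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(da=st.floats(-10, 10, allow_nan=False),
           db=st.floats(-10, 10, allow_nan=False))
    def test_exhaustive_and_symmetric(self, da, db):
        cat = classify_interaction(da, db)
        assert cat in INTERACTION_CATEGORIES
        assert cat == classify_interaction(db, da)

    def test_within_eps_counts_as_zero(self):
        assert classify_interaction(5e-7, -5e-7) == "neutral"
        assert classify_interaction(5e-7, -0.1) == "amensal"


class TestUsePattern:
    @pytest.mark.parametrize("consumers,producers,expected", [
        ({"AF"}, set(), "single-use"),
        ({"AF", "LP"}, set(), "co-consumed"),
        ({"LB"}, {"AP"}, "cross-fed"),
        (set(), {"AP"}, "single-produced"),
        (set(), {"AF", "AP"}, "coproduced"),
        (set(), set(), None),
    ])
    def test_rule_table(self, consumers, producers, expected):
        assert classify_use_pattern("m", consumers, producers) == expected

    def test_cross_fed_requires_distinct_consumer(self):
        # consumers ⊆ producers cannot happen from net fluxes, but the
        # rule still resolves deterministically
        assert classify_use_pattern("m", {"AP"}, {"AP", "AT"}) == \
            "coproduced"


class TestFrequencies:
    def _record(self, met, pattern, i):
        return UsePatternRecord(metabolite=met, category="other",
                                community=frozenset({f"c{i}"}),
                                medium="base", pattern=pattern,
                                consumers=frozenset(), producers=frozenset())

    def test_formula_arithmetic(self):
        recs = [self._record("m", "cross-fed", i) for i in range(3)] + \
               [self._record("m", "co-consumed", 10 + i) for i in range(9)]
        freqs = use_pattern_frequencies(recs)
        assert freqs["m"]["cross-fed"] == pytest.approx(0.25, abs=1e-15)

    def test_single_occurrence_is_frequency_one(self):
        freqs = use_pattern_frequencies([self._record("m", "single-use", 0)])
        assert freqs["m"]["single-use"] == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(counts=st.lists(st.tuples(st.sampled_from(USE_PATTERNS),
                                     st.integers(1, 5)),
                           min_size=1, max_size=8))
    def test_frequencies_sum_to_one(self, counts):
        recs, i = [], 0
        for pattern, n in counts:
            for _ in range(n):
                recs.append(self._record("m", pattern, i))
                i += 1
        freqs = use_pattern_frequencies(recs)
        assert sum(freqs["m"].values()) == pytest.approx(1.0, abs=1e-12)


class TestFluxDerivedStats:
    """Checks on real solved communities against hand recounts."""

    def test_shared_glucose_is_co_consumed(self, glc_medium):
        pool = [sc.make_species("A", ["glc"], 0.1),
                sc.make_species("B", ["glc"], 0.12)]
        com = sc.build_community(pool)
        sc.apply_medium(com, glc_medium)
        sol = sc.steadycom_max_growth(com)
        cons, prods = consumers_and_producers(sol)["glc_u"]
        if len(cons) == 2:  # winner-take-all split may exclude one member
            assert classify_use_pattern("glc_u", cons, prods) == \
                "co-consumed"
        counts = count_overlapping_inputs(sol)
        assert counts["community_count"] == \
            sum(1 for (c, _) in consumers_and_producers(sol).values()
                if len(c) >= 2)

    def test_overlap_counts_two_members_one_substrate(self, glc_medium):
        pool = [sc.make_species("A", ["glc"], 0.1, {"v1": 1.0, "v2": 2.0}),
                sc.make_species("B", ["glyc"], 0.1, {"v1": 2.0, "v2": 1.0})]
        com = sc.build_community(pool)
        sc.apply_medium(com, sc.Medium("m", {
            "glc_e": 1000.0, "glyc_e": 1000.0, "nh4_e": 1000.0,
            "v1_e": 3.0, "v2_e": 3.0}))
        sol = sc.steadycom_max_growth(com)
        counts = count_overlapping_inputs(sol)
        # both consume v1, v2 and nh4; carbons are disjoint
        assert counts["community_count"] == 3
        assert counts["pairwise_max"] == 3

    def test_disjoint_diets_have_zero_overlap(self):
        pool = [sc.make_species("A", ["glc"], 0.1),
                sc.make_species("B", ["glyc"], 0.2)]
        com = sc.build_community(pool)
        # ammonia split would be shared: give each its own huge allowance
        # and drop nh4 need by providing it amply — overlap on nh4 remains,
        # so restrict the count to carbon sources via a no-nh4 construction
        sc.apply_medium(com, sc.Medium("m", {"glc_e": 10.0, "glyc_e": 10.0,
                                             "nh4_e": 1000.0}))
        sol = sc.steadycom_max_growth(com)
        cp = consumers_and_producers(sol)
        assert len(cp["glc_u"][0]) <= 1
        assert len(cp["glyc_u"][0]) <= 1

    def test_richness_counts_and_errors(self, glc_medium):
        model = sc.make_species("A", ["glc"], 0.1, secretions={"ac": 2.0})
        com = sc.build_community([model])
        sc.apply_medium(com, glc_medium)
        sol = sc.steadycom_max_growth(com)
        rich = sc.metabolite_richness(sol, "A")
        assert rich == {"n_consumed": 2, "n_released": 1}  # glc+nh4 in, ac out
        with pytest.raises(KeyError):
            sc.metabolite_richness(sol, "ZZ")

    def test_zero_growth_member_has_zero_richness(self):
        model = sc.make_species("A", ["glc"], 0.1)
        com = sc.build_community([model])
        sc.apply_medium(com, sc.Medium("empty", {}))
        sol = sc.steadycom_max_growth(com)
        assert sc.metabolite_richness(sol, "A") == {"n_consumed": 0,
                                                    "n_released": 0}

    def test_internally_consumed_metabolite_not_host_available(
            self, glc_medium):
        """A cross-fed metabolite fully consumed inside the lumen shows no
        net community exchange, so it is not available to the host."""
        pa = sc.make_species("PA", ["glc"], 0.1, secretions={"paux": 2.0})
        pb = sc.make_species("PB", ["glc"], 0.2, {"paux": 1.0})
        com = sc.build_community([pa, pb])
        sc.apply_medium(com, glc_medium)
        sol = sc.steadycom_max_growth(com)
        solutions = {frozenset({"PA", "PB"}): sol}
        host = sc.host_available_outputs(solutions)
        mets = {r.metabolite for r in host}
        # production 2·0.5 = 1.0 = consumption 1·1.0: nothing escapes
        assert "paux_e" not in mets

    def test_pure_secretion_is_host_available_everywhere(self, glc_medium):
        model = sc.make_species("A", ["glc"], 0.1, secretions={"ac": 2.0})
        per_medium = {}
        for name in ("minimal", "base", "rich"):
            com = sc.build_community([model])
            sc.apply_medium(com, sc.Medium(name, {"glc_e": 10.0,
                                                  "nh4_e": 1000.0}))
            sol = sc.steadycom_max_growth(com)
            per_medium[name] = sc.host_available_outputs(
                {frozenset({"A"}): sol})
        summary = host_output_summary(per_medium)
        for name in ("minimal", "base", "rich"):
            assert "ac_e" in summary[name]
        assert "ac_e" in summary["intersection"]

    def test_role_profile_committed_producer(self, glc_medium):
        model = sc.make_species("A", ["glc"], 0.1, secretions={"ac": 2.0})
        com = sc.build_community([model])
        sc.apply_medium(com, glc_medium)
        sol = sc.steadycom_max_growth(com)
        prof = sc.role_profile({frozenset({"A"}): sol}, "A")
        assert prof["ac_e"]["producer_frequency"] == 1.0
        assert prof["ac_e"]["consumer_frequency"] == 0.0
        assert prof["glc_e"]["consumer_frequency"] == 1.0
        with pytest.raises(KeyError):
            sc.role_profile({frozenset({"A"}): sol}, "ZZ")
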
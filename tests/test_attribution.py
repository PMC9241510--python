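"""Cause attribution: site groups, ANOVA/MANOVA conventions, accounting, ranking."""

import numpy as np
import pandas as pd
import pytest

import guildnet as gn
from guildnet.attribution import site_groups, CAUSE_INTERACTION


def _occ_from_sets(site_ids, a_sites, b_sites):
    presence = pd.DataFrame(0, index=["A", "B"], columns=site_ids, dtype=np.int8)
    presence.loc["A", list(a_sites)] = 1
    presence.loc["B", list(b_sites)] = 1
    return presence


def _pair_row(cls):
    return pd.Series({"taxon_a": "A", "taxon_b": "B", "classification": cls})


class TestSiteGroups:
    def test_segregated_allotypic_sites(self):
        occ = _occ_from_sets(list("12345"), {"1", "2", "3"}, {"3", "4", "5"})
        g = site_groups(_pair_row("segregated"), occ)
        assert set(g.group_1) == {"1", "2"} and set(g.group_2) == {"4", "5"}

    def test_aggregated_both_vs_empty(self):
        occ = _occ_from_sets(list("1234"), {"1", "2"}, {"1", "2"})
        g = site_groups(_pair_row("aggregated"), occ)
        assert set(g.group_1) == {"1", "2"} and set(g.group_2) == {"3", "4"}

    def test_degenerate_group_flags_untestable(self):
        occ = _occ_from_sets(list("123456"), {"1"}, {"2", "3", "4", "5", "6"})
        with pytest.warns(UserWarning, match="untestable"):
            g = site_groups(_pair_row("segregated"), occ)
        assert not g.testable

    def test_random_pair_rejected(self):
        occ = _occ_from_sets(list("1234"), {"1"}, {"2"})
        with pytest.raises(ValueError):
            site_groups(_pair_row("random"), occ)


class TestOneWayAnova:
    def test_hand_computed_F(self):
        F, p = gn.one_way_anova(np.array([1, 2, 3, 2, 3, 4.0]),
                                np.array([0, 0, 0, 1, 1, 1]))
        assert F == pytest.approx(1.5)  # SSB=1.5, SSW/4=1

    def test_identical_groups_p_one(self):
        F, p = gn.one_way_anova(np.array([5.0] * 6), np.array([0, 0, 0, 1, 1, 1]))
        assert p == 1.0 and F == 0.0

    def test_perfect_separation_sentinel(self):
        F, p = gn.one_way_anova(np.array([0, 0, 0, 0, 10, 10, 10, 10.0]),
                                np.array([0] * 4 + [1] * 4))
        assert p == 0.0 and np.isinf(F)

    def test_agrees_with_scipy(self):
        from scipy.stats import f_oneway
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        F, p = gn.one_way_anova(np.concatenate([x, y]),
                                np.array([0] * 12 + [1] * 9))
        ref = f_oneway(x, y)
        assert F == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestOneWayManova:
    toy_g1 = np.array([[0, 0], [1, 0], [0, 1.0]])
    toy_g2 = np.array([[1, 1], [0, 0.9], [1.1, 0]])

    def test_toy_points_not_significant(self):
        stat, p = gn.one_way_manova(np.vstack([self.toy_g1, self.toy_g2]),
                                    np.array([0, 0, 0, 1, 1, 1]))
        assert p > 0.05

    def test_agrees_with_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA
        X = np.vstack([self.toy_g1, self.toy_g2])
        groups = np.array([0, 0, 0, 1, 1, 1])
        stat, p = gn.one_way_manova(X, groups)
        df = pd.DataFrame({"y1": X[:, 0], "y2": X[:, 1], "g": groups})
        res = MANOVA.from_formula("y1 + y2 ~ g", data=df).mv_test()
        tbl = res.results["g"]["stat"]
        assert stat == pytest.approx(tbl.loc["Pillai's trace", "Value"], rel=1e-8)
        assert p == pytest.approx(tbl.loc["Pillai's trace", "Pr > F"], rel=1e-8)

    def test_separated_clouds_significant(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal([0, 0], 0.1, (5, 2))
        g2 = rng.normal([10, 10], 0.1, (5, 2))
        _, p = gn.one_way_manova(np.vstack([g1, g2]), np.array([0] * 5 + [1] * 5))
        assert p < 1e-6

    def test_identical_point_sets_statistic_zero(self):
        pts = np.array([[0, 0], [1, 2], [3, 1.0]])
        stat, _ = gn.one_way_manova(np.vstack([pts, pts]),
                                    np.array([0, 0, 0, 1, 1, 1]))
        assert stat == pytest.approx(0.0, abs=1e-12)


class TestAttributePairs:
    @staticmethod
    def _planted_run(seed=0):
        sites = gn.generate_sites(200, seed=seed)
        species = [
            # off-centre niche: a mean-difference ANOVA cannot see a niche at
            # the middle of the covariate range, so plant it near one end
            gn.SpeciesSpec("envA", niche_var="pH", niche_center=8.5,
                           niche_width=0.5, niche_height=7.0),
            gn.SpeciesSpec("envB", niche_var="pH", niche_center=8.5,
                           niche_width=0.5, niche_height=7.0),
            gn.SpeciesSpec("intA"),
            gn.SpeciesSpec("intB", baseline_logit=-1.0),
        ]
        inter = [gn.InteractionSpec(("intA", "intB"), +1, 4.0)]
        occ, truth = gn.simulate_occurrence(sites, species, inter, seed=seed + 1)
        pairs = gn.test_all_pairs(occ)
        attrib = gn.attribute_pairs(pairs, occ, sites, env_correction="bh")
        return pairs, attrib

    def test_shared_niche_pair_explained_by_environment(self):
        hits = 0
        for seed in range(5):
            _, attrib = self._planted_run(seed)
            row = attrib[(attrib["taxon_a"] == "envA") & (attrib["taxon_b"] == "envB")]
            if len(row) and "pH" in row.iloc[0]["explaining_vars"]:
                hits += 1
        assert hits >= 4

    def test_planted_interaction_recovered(self):
        hits = 0
        for seed in range(10):
            _, attrib = self._planted_run(seed)
            row = attrib[(attrib["taxon_a"] == "intA") & (attrib["taxon_b"] == "intB")]
            if len(row) and row.iloc[0]["final_cause"] == CAUSE_INTERACTION:
                hits += 1
        assert hits >= 7

    def test_accounting_conservation(self, bernoulli_occ):
        occ = bernoulli_occ(25, 120, seed=4)
        sites = gn.generate_sites(120, seed=4)
        sites.index = occ.columns
        pairs = gn.test_all_pairs(occ)
        attrib = gn.attribute_pairs(pairs, occ, sites)
        n_nonrandom = int(((pairs["classification"] != "random")
                           & pairs["testable"]).sum())
        summary = gn.attribution_summary(attrib, n_nonrandom)
        assert sum(summary["causes"].values()) == len(attrib) == n_nonrandom

    def test_null_env_attribution_rate_near_alpha(self):
        from guildnet.experiments import null_attribution_rate
        res = null_attribution_rate(n_reps=200, n_sites=100, seed=0)
        n = res["n_pairs"]
        se = np.sqrt(0.05 * 0.95 / n)
        for var, rate in res["per_variable_rates"].items():
            assert abs(rate - 0.05) < 3 * se + 1e-9, (var, rate)

    def test_incomplete_env_rejected(self, bernoulli_occ):
        occ = bernoulli_occ(4, 20, seed=0)
        sites = gn.generate_sites(20, seed=0)
        sites.index = occ.columns
        sites.loc[sites.index[0], "pH"] = np.nan
        pairs = gn.test_all_pairs(occ)
        with pytest.raises(ValueError):
            gn.attribute_pairs(pairs, occ, sites)


class TestRankVariables:
    @staticmethod
    def _attrib(rows):
        env = ["pH", "DOC"]
        recs = []
        for i, (expl, disp) in enumerate(rows):
            rec = {"taxon_a": f"a{i}", "taxon_b": f"b{i}",
                   "classification": "aggregated", "n_group_1": 5, "n_group_2": 5,
                   "manova_p": 0.01 if disp else 0.9,
                   "explaining_vars": ",".join(sorted(expl)),
                   "dispersal": disp, "testable": True}
            for v in env:
                rec[f"p_{v}"] = 0.01 if v in expl else 0.5
            if expl and disp:
                rec["final_cause"] = "environment+dispersal"
            elif expl:
                rec["final_cause"] = "environment"
            elif disp:
                rec["final_cause"] = "dispersal"
            else:
                rec["final_cause"] = "interaction"
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_single_variable_covers_all(self):
        att = self._attrib([({"pH"}, False)] * 4)
        rk = gn.rank_variables(att, "cooccurrence")
        assert rk.iloc[0]["variable"] == "pH"
        assert rk.iloc[0]["cumulative_prop"] == 1.0
        assert (rk.iloc[1:]["n_new"] == 0).all()

    def test_greedy_set_cover_on_three_pairs(self):
        # pair0: pH only; pair1: pH and DOC; pair2: DOC only
        att = self._attrib([({"pH"}, False), ({"pH", "DOC"}, False), ({"DOC"}, False)])
        rk = gn.rank_variables(att, "cooccurrence")
        # both variables explain 2 pairs; lexicographic tie-break puts DOC first
        assert list(rk["variable"]) == ["DOC", "pH"]
        assert list(rk["n_new"]) == [2, 1]
        np.testing.assert_allclose(rk["cumulative_prop"], [2 / 3, 1.0])

    def test_dispersal_only_proportion_reported(self):
        att = self._attrib([({"pH"}, False), (set(), True), (set(), False)])
        rk = gn.rank_variables(att, "cooccurrence")
        assert rk.iloc[0]["prop_dispersal_only"] == pytest.approx(1 / 3)

    def test_empty_attributions_warn(self):
        att = self._attrib([({"pH"}, False)])
        with pytest.warns(UserWarning, match="no testable"):
            rk = gn.rank_variables(att, "coexclusion")
        assert rk.empty
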
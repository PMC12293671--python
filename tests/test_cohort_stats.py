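import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from octamorph.cohort_stats import (GroupSample, dunn_posthoc, kruskal_wallis,
                                    normality_gate, one_way_anova,
                                    render_pairwise_table, run_full_comparison,
                                    spearman_correlation, tukey_posthoc)

FIX3 = [GroupSample("a", (1, 2, 3)), GroupSample("b", (4, 5, 6)),
        GroupSample("c", (7, 8, 9))]


def _gaussian_groups(seed, sizes=(17, 14, 18, 20), shift=0.0):
    rng = np.random.default_rng(seed)
    out = []
    for i, (name, n) in enumerate(zip("abcd", sizes)):
        out.append(GroupSample(name, tuple(rng.normal(i * shift, 1.0, n))))
    return out


class TestNormalityGate:
    def test_gaussian_groups_mostly_route_to_anova(self):
        hits = sum(normality_gate(_gaussian_groups(s)) == "anova" for s in range(100))
        assert hits >= 75  # Shapiro false-positive rate over 4 groups

    def test_lognormal_group_routes_to_kruskal(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            gs = [GroupSample(g, tuple(rng.normal(0, 1, n)))
                  for g, n in zip("abc", (17, 14, 20))]
            gs.append(GroupSample("d", tuple(rng.lognormal(0, 1, 18))))
            hits += normality_gate(gs) == "kruskal_wallis"
        assert hits >= 85

    def test_constant_groups_degenerate(self):
        gs = [GroupSample("a", (1.0,) * 5), GroupSample("b", (2.0,) * 5)]
        with pytest.warns(UserWarning, match="zero variance"):
            assert normality_gate(gs) == "kruskal_wallis"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([GroupSample("a", (1, 2)), GroupSample("b", (1, 2, 3))])


class TestAnova:
    def test_study_sized_groups_df(self):
        res = one_way_anova(_gaussian_groups(0))
        assert res.df == (3, 65)

    def test_identical_groups_f_zero(self):
        g = GroupSample("a", (1.0, 2.0, 3.0))
        res = one_way_anova([g, GroupSample("b", (1.0, 2.0, 3.0))])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_sums_of_squares(self):
        groups = [GroupSample("a", (1, 2, 3)), GroupSample("b", (2, 3, 4)),
                  GroupSample("c", (3, 4, 5))]
        res = one_way_anova(groups)
        # SSB = 6 (df 2), SSW = 6 (df 6) -> F = 3 / 1 = 3
        assert res.statistic == pytest.approx(3.0)
        assert res.df == (2, 6)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([GroupSample("a", (1.0, 1.0)), GroupSample("b", (1.0, 1.0))])


class TestKruskalWallis:
    def test_hand_computed_fixture(self):
        # ranks 1..9, mean ranks 2/5/8: H = 12/(9*10) * 3*(9+0+9) = 7.2
        res = kruskal_wallis(FIX3)
        assert res.statistic == pytest.approx(7.2)
        assert res.df == (2,)
        assert res.p_value == pytest.approx(1 - sps.chi2.cdf(7.2, 2))

    def test_four_groups_df(self):
        res = kruskal_wallis(_gaussian_groups(1))
        assert res.df == (3,)

    def test_group_order_invariance(self):
        a = kruskal_wallis(FIX3).statistic
        b = kruskal_wallis(FIX3[::-1]).statistic
        assert a == pytest.approx(b)

    def test_rank_invariance_under_scaling(self):
        scaled = [GroupSample(g.group, tuple(17.3 * v for v in g.values))
                  for g in FIX3]
        assert kruskal_wallis(scaled).statistic == pytest.approx(7.2)


class TestDunn:
    def test_pair_count(self):
        assert len(dunn_posthoc(_gaussian_groups(0))) == 6

    def test_bonferroni_cap(self):
        res = dunn_posthoc(_gaussian_groups(2))  # null data: large raw p
        assert all(0 <= r.adjusted_p <= 1 for r in res)
        assert any(r.adjusted_p == 1.0 for r in res)

    def test_hand_computed_extreme_pair(self):
        # mean ranks 2 vs 8, N=9: z = -6/sqrt(7.5*(2/3)) = -6/sqrt(5)
        res = {r.pair: r.adjusted_p for r in dunn_posthoc(FIX3)}
        z = 6 / math.sqrt(5)
        expected = min(1.0, 3 * 2 * sps.norm.sf(z))
        assert res[("a", "c")] == pytest.approx(expected, abs=1e-12)
        assert res[("a", "c")] == pytest.approx(0.021877, abs=1e-5)

    def test_adjusted_at_least_unadjusted(self):
        bon = dunn_posthoc(_gaussian_groups(3), adjust="bonferroni")
        holm = dunn_posthoc(_gaussian_groups(3), adjust="holm")
        for b, h in zip(bon, holm):
            assert b.adjusted_p >= h.adjusted_p - 1e-12  # holm uniformly <= bonferroni

    def test_scaling_leaves_dunn_unchanged(self):
        base = dunn_posthoc(FIX3)
        scaled = dunn_posthoc([GroupSample(g.group, tuple(3.7 * v for v in g.values))
                               for g in FIX3])
        for a, b in zip(base, scaled):
            assert a.adjusted_p == pytest.approx(b.adjusted_p, abs=1e-15)


class TestTukey:
    def test_equal_mean_groups_p_near_one(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        res = tukey_posthoc([GroupSample("a", tuple(base)),
                             GroupSample("b", tuple(base + 1e-12))])
        assert res[0].adjusted_p > 0.999

    def test_pair_count(self):
        assert len(tukey_posthoc(_gaussian_groups(0))) == 6

    def test_studentized_range_quantile_decision(self):
        # balanced 3 groups, n=3, MSE=1, df_err=6: reject iff
        # q_obs = |diff| / sqrt(MSE/n) > q(0.05; 3, 6) = 4.34
        groups = [GroupSample("a", (0, 1, 2)), GroupSample("b", (1, 2, 3)),
                  GroupSample("c", (4, 5, 6))]
        res = {r.pair: r.adjusted_p for r in tukey_posthoc(groups)}
        se = math.sqrt(1.0 / 3)
        q_ab, q_ac = 1.0 / se, 4.0 / se       # 1.73 and 6.93
        assert q_ab < 4.34 < q_ac
        assert res[("a", "b")] > 0.05
        assert res[("a", "c")] < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            tukey_posthoc([GroupSample("a", (1.0, 1.0)), GroupSample("b", (2.0, 2.0))])


class TestSpearman:
    def test_monotone_extremes(self):
        x = (1, 2, 3, 4, 5)
        assert spearman_correlation(x, x).rho == pytest.approx(1.0)
        assert spearman_correlation(x, x[::-1]).rho == pytest.approx(-1.0)

    def test_hand_rank_fixture(self):
        # sum d^2 = 4, n = 4: rho = 1 - 6*4/(4*15) = 0.6
        res = spearman_correlation((1, 2, 3, 4), (2, 1, 4, 3))
        assert res.rho == pytest.approx(0.6)
        assert res.n == 4

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            spearman_correlation((1, 1, 1, 1), (1, 2, 3, 4))
        with pytest.raises(ValueError):
            spearman_correlation((1, 2), (3, 4))


class TestRunFullComparison:
    @pytest.fixture()
    def cohort(self):
        from octamorph.synthetic import CohortSpec, generate_cohort
        return generate_cohort(CohortSpec(seed=7))

    def test_report_shape_and_gating(self, cohort):
        report = run_full_comparison(cohort, ["fd", "faz_area_mm2"])
        for param, res in report.items():
            om = res["omnibus"]
            assert om.test in ("anova", "kruskal_wallis")
            assert 0 <= om.p_value <= 1
            if res["posthoc"] is not None:
                assert len(res["posthoc"]) == 6
                assert om.p_value < 0.05
            else:
                assert om.p_value >= 0.05
        # FD has a strong severity gradient; FAZ area does not
        assert report["fd"]["posthoc"] is not None

    def test_long_table_rendering(self, cohort):
        report = run_full_comparison(cohort, ["fd"])
        tab = render_pairwise_table(report)
        assert set(tab["parameter"]) == {"fd"}
        assert len(tab) in (1, 6)

    def test_missing_column_rejected(self, cohort):
        with pytest.raises(KeyError):
            run_full_comparison(cohort, ["nonexistent_metric"])
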
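"""Survey statistics: CPUE strata, Welch tests, sex ratios, length-weight fits."""

import numpy as np
import pytest
from scipy import stats as sps

from lfqassess import TrapSet
from lfqassess.stats import (
    allometry_test,
    compare_lwr_sexes,
    cpue_by_stratum,
    fit_lwr,
    pairwise_welch_bonferroni,
    sex_ratio_chisq,
    welch_anova,
)

from conftest import make_records


class TestCpue:
    def test_single_set_cpue(self, small_survey):
        sets, records = small_survey
        out = cpue_by_stratum(sets, [r for r in records if r.set_id == "A"])
        row = out[out["stratum_lo"] == 40.0].iloc[0]
        assert row["cpue_mean"] == pytest.approx(30 / 15)

    def test_zero_catch_sets_enter_the_mean(self, small_survey):
        sets, records = small_survey
        out = cpue_by_stratum(sets, records)
        # stratum 80-100 holds sets B (5/15) and C (0/10)
        row = out[out["stratum_lo"] == 80.0].iloc[0]
        assert row["n_sets"] == 2
        assert row["cpue_mean"] == pytest.approx((5 / 15 + 0.0) / 2)

    def test_total_conservation(self, small_survey):
        sets, records = small_survey
        out = cpue_by_stratum(sets, records)
        # sets A and C have 15 and 10 traps but grouping is by set: check the
        # identity sum(per-set cpue * traps) = total records via per-stratum sums
        assert out["n_sets"].sum() == 3

    def test_record_for_missing_or_invalid_set_errors(self, small_survey):
        sets, records = small_survey
        with pytest.raises(ValueError, match="missing"):
            cpue_by_stratum(sets, records + make_records([99.0], set_id="ZZ"))
        sets2 = sets + [TrapSet("D", sets[0].date, 60.0, valid=False)]
        with pytest.raises(ValueError, match="invalid"):
            cpue_by_stratum(sets2, records + make_records([99.0], set_id="D"))


class TestWelch:
    def test_two_groups_equals_squared_welch_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.7, 2.5, 14)
        f, df1, df2, p = welch_anova([a, b])
        t, pt = sps.ttest_ind(a, b, equal_var=False)
        assert f == pytest.approx(t**2, abs=1e-9)
        assert p == pytest.approx(pt, abs=1e-9)

    def test_identical_groups_give_zero_f(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        f, _, _, p = welch_anova([g, g.copy(), g.copy()])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_three_group_fixture_matches_independent_oracle(self):
        groups = [
            np.array([3.1, 2.8, 3.5, 3.0, 2.9]),
            np.array([4.2, 4.9, 3.8, 4.4]),
            np.array([2.0, 2.3, 1.7, 2.6, 2.2, 1.9]),
        ]
        f, df1, df2, p = welch_anova(groups)
        # value frozen from the published Welch formula computed by hand
        assert f == pytest.approx(34.7531, abs=0.01)
        assert df1 == 2
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [len(g) for g in groups]),
            }
        )
        ref = pingouin.welch_anova(data=df, dv="y", between="g").iloc[0]
        assert f == pytest.approx(ref["F"], abs=1e-6)
        assert df2 == pytest.approx(ref["ddof2"], abs=1e-6)
        assert p == pytest.approx(ref["p_unc"], abs=1e-9)

    def test_zero_variance_group_errors(self):
        with pytest.raises(ValueError):
            welch_anova([np.array([1.0, 1.0]), np.array([1.0, 2.0])])


class TestPairwise:
    def test_identical_groups_share_a_letter(self):
        g = np.array([1.0, 2.0, 3.0, 2.0])
        padj, letters = pairwise_welch_bonferroni([g, g.copy(), g.copy()])
        assert (padj.to_numpy() == 1.0).all()
        assert len(set(letters)) == 1

    def test_strongly_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(1)
        base = [rng.normal(0, 1, 15) for _ in range(2)]
        shifted = rng.normal(10, 1, 15)  # ten standard deviations away
        _, letters = pairwise_welch_bonferroni(base + [shifted])
        assert set(letters[2]).isdisjoint(set(letters[0]))
        assert set(letters[0]) & set(letters[1])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        gs = [rng.normal(m, 1, 12) for m in (0.0, 0.4, 1.0)]
        padj, _ = pairwise_welch_bonferroni(gs)
        for i in range(3):
            for j in range(i + 1, 3):
                _, raw = sps.ttest_ind(gs[i], gs[j], equal_var=False)
                assert padj.iloc[i, j] >= raw - 1e-15


class TestSexRatio:
    def test_balanced(self):
        ratio, chi2, p = sex_ratio_chisq(50, 50)
        assert (ratio, chi2, p) == (1.0, 0.0, 1.0)

    def test_skewed(self):
        _, chi2, _ = sex_ratio_chisq(25, 75)
        assert chi2 == pytest.approx(25.0)

    def test_ratio_reported_per_female(self):
        ratio, _, _ = sex_ratio_chisq(61, 100)
        assert ratio == pytest.approx(0.61)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sex_ratio_chisq(0, 0)


class TestLwr:
    def test_exact_power_law_recovered(self):
        L = np.linspace(40, 170, 30)
        w = 0.002 * L**2.812
        recs = make_records(L, weights=list(w))
        fit = fit_lwr(recs, "pooled")
        assert fit.a == pytest.approx(0.002, rel=1e-9)
        assert fit.b == pytest.approx(2.812, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_isometric_data_not_rejected(self):
        rng = np.random.default_rng(5)
        L = rng.uniform(40, 170, 200)
        w = 0.0015 * L**3 * np.exp(rng.normal(0, 0.05, 200))
        t, p = allometry_test(fit_lwr(make_records(L, weights=list(w))))
        assert p > 0.05

    @pytest.mark.parametrize("b,se,t_expected", [(2.839, 0.027, -5.96),
                                                 (2.812, 0.021, -8.95)])
    def test_allometry_t_statistic(self, b, se, t_expected):
        from lfqassess.stats import LWRFit

        fit = LWRFit(group="pooled", n=411, a=0.002, b=b, se_log_a=0.1,
                     se_b=se, r_squared=0.98)
        t, p = allometry_test(fit)
        assert t == pytest.approx(t_expected, abs=0.005)
        assert p < 0.001

    def test_slope_recovery_with_lognormal_error(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            L = rng.uniform(40, 170, 400)
            w = 0.002 * L**2.812 * np.exp(rng.normal(0, 0.1, 400))
            fit = fit_lwr(make_records(L, weights=list(w)))
            if abs(fit.b - 2.812) < 2 * fit.se_b:
                hits += 1
        assert hits >= 18  # 90% of 20 seeds

    def test_too_few_records_errors(self):
        with pytest.raises(ValueError):
            fit_lwr(make_records([50.0], weights=[100.0]))


class TestSexComparison:
    @staticmethod
    def _sexed(seed, offset=0.0, slope_delta=0.0, n=400, sigma=0.1):
        rng = np.random.default_rng(seed)
        recs = []
        for sex, off, db in (("male", 0.0, 0.0), ("female", offset, slope_delta)):
            L = rng.uniform(40, 170, n)
            w = np.exp(
                np.log(0.002) + off + (2.812 + db) * np.log(L)
                + rng.normal(0, sigma, n)
            )
            recs += make_records(L, weights=list(w), sex=sex)
        return recs

    def test_identical_sexes_nothing_detected(self):
        res = compare_lwr_sexes(self._sexed(0))
        assert res["interaction_p"] > 0.05
        assert res["sex_p"] > 0.01
        lo, hi = res["offset_ci"]
        assert lo < 0 < hi

    def test_female_offset_recovered(self):
        """A +0.08 log-scale offset with common slope is found and covered."""
        covered = parallel = 0
        for seed in range(20):
            res = compare_lwr_sexes(self._sexed(seed, offset=0.08))
            lo, hi = res["offset_ci"]
            covered += lo <= 0.08 <= hi
            parallel += res["interaction_p"] > 0.05
        assert covered >= 18
        assert parallel >= 18

    def test_unequal_slopes_detected(self):
        res = compare_lwr_sexes(self._sexed(1, slope_delta=0.3))
        assert res["interaction_p"] < 0.05

    def test_single_sex_errors(self):
        recs = make_records([50, 60, 70], weights=[100.0, 150, 200], sex="male")
        with pytest.raises(ValueError):
            compare_lwr_sexes(recs)
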
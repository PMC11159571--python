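"""Group contrasts, Bonferroni, Pearson CI and scan-rescan agreement."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import meniscoq as mq
from meniscoq.errors import ModelError, ValidationError
from meniscoq.phantom import CONTROL_MEDIAL_T2STAR_MS, PATIENT_MEDIAL_T2STAR_MS


class TestCompareGroups:
    def test_null_simulation_keeps_pvalues_high(self):
        """Identically distributed groups: p > 0.05 in at least 90/100 replicates."""
        high = 0
        for i in range(100):
            tab = mq.simulate_group_table(seed=1_000 + i, mean_patient=10.0,
                                          sd_patient=1.3, mean_control=10.0, sd_control=1.3)
            high += mq.compare_groups(tab, region="PH", side="medial").pvalue > 0.05
        assert high >= 90

    def test_overwhelming_shift_always_significant(self):
        for i in range(20):
            tab = mq.simulate_group_table(seed=2_000 + i, mean_patient=16.5,
                                          sd_patient=1.3, mean_control=10.0, sd_control=1.3)
            assert mq.compare_groups(tab, region="PH", side="medial").pvalue < 1e-3

    def test_pooled_regions_use_mixed_model(self):
        tab = mq.simulate_cohort_table(
            7, PATIENT_MEDIAL_T2STAR_MS, CONTROL_MEDIAL_T2STAR_MS
        )
        res = mq.compare_groups(tab, side="medial")
        assert res.method == "mixedlm"
        assert res.n_obs == 30 * 4
        assert res.estimate > 0  # patients elevated on average

    def test_single_row_per_subject_collapses_to_ols(self):
        tab = mq.simulate_group_table(seed=3, mean_patient=12.0, sd_patient=1.0,
                                      mean_control=9.0, sd_control=1.0)
        res = mq.compare_groups(tab, region="PH", side="medial")
        assert res.method == "ols"
        assert res.n_subjects == 30

    def test_single_group_rejected(self):
        tab = mq.simulate_group_table(seed=4, mean_patient=12.0, sd_patient=1.0,
                                      mean_control=9.0, sd_control=1.0)
        with pytest.raises(ModelError):
            mq.compare_groups(tab[tab.group == "patient"], region="PH")

    def test_missing_covariate_rejected(self):
        tab = mq.simulate_group_table(seed=5, mean_patient=12.0, sd_patient=1.0,
                                      mean_control=9.0, sd_control=1.0).drop(columns="bmi")
        with pytest.raises(ModelError):
            mq.compare_groups(tab, region="PH")


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [(0.01, 6, 0.06), (0.5, 6, 1.0), (0.3, 1, 0.3)])
    def test_examples(self, p, m, expected):
        assert mq.bonferroni_pairwise([p], m) == [pytest.approx(expected)]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            mq.bonferroni_pairwise([1.5], 6)

    @settings(derandomize=True, max_examples=60)
    @given(
        ps=st.lists(st.floats(0, 1), min_size=1, max_size=8),
        m1=st.integers(1, 10), m2=st.integers(1, 10),
    )
    def test_never_decreases_and_monotone_in_m(self, ps, m1, m2):
        lo, hi = sorted((m1, m2))
        adj_lo, adj_hi = mq.bonferroni_pairwise(ps, lo), mq.bonferroni_pairwise(ps, hi)
        for p, a, b in zip(ps, adj_lo, adj_hi):
            assert a >= p and b >= a


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.arange(10.0)
        assert mq.pearson_ci(x, 2 * x + 1).r == pytest.approx(1.0)
        assert mq.pearson_ci(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_formula_and_scipy(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=11), rng.normal(size=11)
        res = mq.pearson_ci(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_direct = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        r_sp, p_sp = scipy.stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_sp, abs=1e-12)
        assert res.pvalue == pytest.approx(p_sp, rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            mq.pearson_ci(np.ones(5), np.arange(5.0))

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 60))
    def test_ci_contains_r_and_shrinks_with_n(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        res = mq.pearson_ci(x, y)
        assert res.ci_low <= res.r <= res.ci_high
        big = mq.pearson_ci(np.tile(x, 4), np.tile(y, 4))
        assert (big.ci_high - big.ci_low) < (res.ci_high - res.ci_low)


class TestAgreement:
    def test_identical_scans_give_perfect_agreement(self):
        x = np.array([8.1, 9.3, 10.2, 11.0, 12.5, 7.9])
        res = mq.icc_absolute_agreement(x, x.copy())
        assert res.icc == 1.0
        ba = res.bland_altman
        assert ba.mean_difference == 0.0
        assert ba.lower_loa == 0.0 and ba.upper_loa == 0.0

    def test_constant_offset_penalized_despite_perfect_correlation(self):
        x = np.array([8.1, 9.3, 10.2, 11.0, 12.5, 7.9])
        res = mq.icc_absolute_agreement(x, x + 2.0)
        assert res.icc < 1.0
        assert mq.pearson_ci(x, x + 2.0).r == pytest.approx(1.0)

    def test_offset_to_both_scans_leaves_icc_unchanged(self):
        rng = np.random.default_rng(15)
        s1 = rng.normal(10, 1.5, 9)
        s2 = s1 + rng.normal(0, 0.5, 9)
        base = mq.icc_absolute_agreement(s1, s2).icc
        shifted = mq.icc_absolute_agreement(s1 + 3.3, s2 + 3.3).icc
        assert shifted == pytest.approx(base, abs=1e-12)
        one_sided = mq.icc_absolute_agreement(s1 + 3.3, s2).icc
        assert one_sided < base

    def test_matches_anova_table_oracle(self):
        """ICC(A,1) from an explicitly assembled two-way ANOVA table, 1e-10."""
        rng = np.random.default_rng(3)
        s1 = rng.normal(10, 1.5, 8)
        s2 = s1 + rng.normal(0.2, 0.4, 8)
        res = mq.icc_absolute_agreement(s1, s2)
        X = np.column_stack([s1, s2])
        n, k = X.shape
        msr = np.var(X.mean(axis=1), ddof=1) * k
        msc = np.var(X.mean(axis=0), ddof=1) * n
        sse = ((X - X.mean(1, keepdims=True) - X.mean(0, keepdims=True) + X.mean()) ** 2).sum()
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
        assert res.icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(23)
        s1 = rng.normal(9.5, 1.2, 10)
        s2 = s1 + rng.normal(0.1, 0.6, 10)
        res = mq.icc_absolute_agreement(s1, s2)
        df = pd.DataFrame({
            "subject": np.tile(np.arange(10), 2),
            "scan": np.repeat([1, 2], 10),
            "value": np.concatenate([s1, s2]),
        })
        ref = pg.intraclass_corr(df, "subject", "scan", "value")
        row = ref[ref.Type == "ICC(A,1)"].iloc[0] if (ref.Type == "ICC(A,1)").any() \
            else ref[ref.Type == "ICC2"].iloc[0]
        assert res.icc == pytest.approx(row.ICC, abs=1e-8)
        lo, hi = row["CI95"] if "CI95" in ref.columns else row["CI95%"]
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_bland_altman_halfwidth_is_196_sd(self):
        rng = np.random.default_rng(31)
        s1 = rng.normal(10, 1.0, 12)
        s2 = s1 + rng.normal(0.3, 0.8, 12)
        ba = mq.icc_absolute_agreement(s1, s2).bland_altman
        assert (ba.upper_loa - ba.mean_difference) / ba.sd_difference == pytest.approx(1.96)
        assert (ba.mean_difference - ba.lower_loa) / ba.sd_difference == pytest.approx(1.96)
        diffs = s2 - s1
        assert ba.mean_difference == pytest.approx(diffs.mean(), abs=1e-12)
        assert ba.sd_difference == pytest.approx(diffs.std(ddof=1), abs=1e-12)

    def test_t_test_matches_scipy(self):
        rng = np.random.default_rng(41)
        s1 = rng.normal(10, 1.0, 10)
        s2 = s1 + rng.normal(0.5, 0.5, 10)
        res = mq.icc_absolute_agreement(s1, s2)
        assert res.t_p == pytest.approx(scipy.stats.ttest_1samp(s2 - s1, 0.0).pvalue, rel=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ModelError):
            mq.icc_absolute_agreement([1.0, 2.0], [1.1, 2.1])
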
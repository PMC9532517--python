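import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from synquant.stats import (
    anova_dunnett_t3,
    anova_tukey,
    fisher_lsd,
    group_summary,
    ks_two_sample,
    normalize_bands,
    percent_change,
    smm_cdf,
    smm_crit,
    welch_t,
)


def welch_by_hand(a, b):
    """Direct transcription of the Welch formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def ks_by_hand(a, b):
    """Brute-force max ECDF gap over all data points."""
    a, b = np.sort(a), np.sort(b)
    gaps = [
        abs(np.searchsorted(a, x, "right") / len(a) - np.searchsorted(b, x, "right") / len(b))
        for x in np.concatenate([a, b])
    ]
    return max(gaps)


class TestNormalizeBands:
    def table(self):
        return pd.DataFrame(
            {
                "sample_id": ["c1", "c2", "t1", "t2"],
                "group": ["ctl", "ctl", "kd", "kd"],
                "target_intensity": [100.0, 120.0, 300.0, 360.0],
                "loading_intensity": [50.0, 60.0, 50.0, 60.0],
            }
        )

    def test_control_fold_change_is_one(self):
        out = normalize_bands(self.table(), "ctl")
        assert out.loc[out["group"] == "ctl", "fold_change"].mean() == pytest.approx(1.0)

    def test_fold_change_values(self):
        out = normalize_bands(self.table(), "ctl")
        np.testing.assert_allclose(out.loc[out["group"] == "kd", "fold_change"], [3.0, 3.0])

    def test_linearity_in_target(self):
        doubled = self.table().assign(target_intensity=lambda d: 2 * d["target_intensity"])
        base = normalize_bands(self.table(), "ctl")
        # doubling every target rescales the control mean too: folds unchanged
        np.testing.assert_allclose(
            normalize_bands(doubled, "ctl")["fold_change"], base["fold_change"]
        )

    def test_zero_loading_rejected(self):
        bad = self.table()
        bad.loc[0, "loading_intensity"] = 0.0
        with pytest.raises(ValueError, match="loading"):
            normalize_bands(bad, "ctl")

    def test_missing_control_group(self):
        with pytest.raises(ValueError, match="control"):
            normalize_bands(self.table(), "nope")


class TestWelchT:
    def test_identical_groups(self):
        report = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert report.statistic == 0.0
        assert report.pvalue == pytest.approx(1.0)

    def test_matches_hand_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        report = welch_t(a, b)
        t, df = welch_by_hand(a, b)
        assert report.statistic == pytest.approx(t, abs=1e-12)
        assert report.df == pytest.approx(df, abs=1e-12)

    def test_unequal_sizes_and_variances(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 4, 7)
        report = welch_t(a, b)
        t, df = welch_by_hand(a, b)
        assert report.statistic == pytest.approx(t)
        assert report.df == pytest.approx(df)

    def test_degenerate_flagged(self):
        report = welch_t([2.0, 2.0], [2.0, 2.0])
        assert report.params["degenerate"]
        assert report.pvalue == 1.0

    @given(a=st.floats(min_value=0.01, max_value=100.0), b=st.floats(-50, 50))
    def test_affine_invariance(self, a, b):
        x = np.array([1.0, 2.5, 3.0, 4.2])
        y = np.array([2.0, 3.5, 5.0])
        r0 = welch_t(x, y)
        r1 = welch_t(a * x + b, a * y + b)
        assert r1.statistic == pytest.approx(r0.statistic, rel=1e-9)
        assert r1.pvalue == pytest.approx(r0.pvalue, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])


class TestKS:
    def test_self_comparison(self):
        report = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert report.statistic == 0.0
        assert report.pvalue == pytest.approx(1.0)

    def test_disjoint_support(self):
        assert ks_two_sample([0, 0, 0], [1, 1, 1]).statistic == 1.0

    def test_matches_ecdf_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(5, 30))
            b = rng.normal(0.5, 2, rng.integers(5, 30))
            assert ks_two_sample(a, b).statistic == pytest.approx(ks_by_hand(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        a, b = rng.normal(2, 1, 15), rng.normal(3, 1, 12)
        assert ks_two_sample(a, b).statistic == pytest.approx(
            ks_two_sample(np.exp(a), np.exp(b)).statistic
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestSMM:
    def test_reduces_to_t_for_one_comparison(self):
        # k=1: P(|T| <= m) is the two-sided t CDF
        from scipy import stats as sps

        for m, df in ((1.5, 7.0), (2.3, 12.5)):
            assert smm_cdf(m, 1, df) == pytest.approx(1 - 2 * sps.t.sf(m, df), abs=1e-6)

    def test_infinite_df_matches_sidak_normal(self):
        # at df=inf the SMM quantile equals the Sidak-corrected normal quantile
        from scipy import stats as sps

        k = 3
        crit = smm_crit(0.05, k, float("inf"))
        sidak = sps.norm.ppf((1 + (1 - 0.05) ** (1 / k)) / 2)
        assert crit == pytest.approx(sidak, abs=1e-6)

    def test_cdf_monotone_in_k(self):
        assert smm_cdf(2.0, 1, 10) > smm_cdf(2.0, 3, 10) > smm_cdf(2.0, 6, 10)


class TestDunnettT3:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0]
        report = anova_dunnett_t3([g, list(g), list(g)])
        assert report.statistic == pytest.approx(0.0, abs=1e-12)
        for comp in report.comparisons:
            assert not comp.significant
            assert comp.pvalue_adjusted == pytest.approx(1.0)

    def test_adjusted_p_never_below_raw(self, rng):
        for _ in range(10):
            groups = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 3), 8) for _ in range(4)]
            report = anova_dunnett_t3(groups)
            for comp in report.comparisons:
                assert comp.pvalue_adjusted >= comp.pvalue - 1e-12

    def test_shifted_group_detected(self, rng):
        groups = [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(2, 1, 15)]
        report = anova_dunnett_t3(groups, control_index=0)
        shifted = [c for c in report.comparisons if c.group_a == "group2"][0]
        assert shifted.significant

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            anova_dunnett_t3([[1.0, 2.0], [3.0, 4.0]])


class TestTukey:
    def test_identical_groups_adjusted_p_near_one(self):
        g = [1.0, 2.0, 3.0]
        report = anova_tukey([g, list(g), list(g)])
        for comp in report.comparisons:
            assert comp.pvalue_adjusted == pytest.approx(1.0, abs=1e-6)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError, match="3 groups"):
            anova_tukey([[1.0, 2.0], [3.0, 4.0]])

    def test_all_pairs_reported(self, rng):
        report = anova_tukey([rng.normal(size=5) for _ in range(4)])
        assert len(report.comparisons) == 6


class TestFisherLSD:
    def test_identical_groups_non_significant(self):
        g = [10.0, 11.0, 12.0]
        report = fisher_lsd([g, list(g), list(g), list(g)])
        assert all(not c.significant for c in report.comparisons)

    def test_matches_pooled_t_for_two_equal_groups(self, rng):
        from scipy import stats as sps

        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        report = fisher_lsd([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert report.comparisons[0].statistic == pytest.approx(t)
        assert report.comparisons[0].pvalue == pytest.approx(p)


class TestSummaries:
    def test_mean_sem_match_direct_computation(self, rng):
        x = rng.normal(5, 2, 40)
        s = group_summary(x)
        assert s.mean == pytest.approx(x.mean(), rel=1e-10)
        assert s.sem == pytest.approx(x.std(ddof=1) / math.sqrt(len(x)), rel=1e-10)

    def test_percent_change(self):
        pc, sem = percent_change([1.16, 1.16], [1.0, 1.0])
        assert pc == pytest.approx(16.0)
        assert sem == 0.0
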
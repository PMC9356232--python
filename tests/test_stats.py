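"""Contingency, ANOVA, correlation, and summary-reconstruction statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lmswell import reference as ref
from lmswell.stats import (
    ReconciliationError,
    anova_from_summary,
    chi_squared,
    oneway_anova,
    pearson_corr_matrix,
    pooled_mean,
    reconstruct_counts,
    standardize,
)


class TestChiSquared:
    def test_independent_table(self):
        assert chi_squared([[10, 10], [10, 10]]).chi2 == pytest.approx(0.0)

    def test_hand_computed(self):
        # 2x2 with all expected cells 15: chi2 = 4 * 25/15 = 20/3
        res = chi_squared([[20, 10], [10, 20]])
        assert res.chi2 == pytest.approx(20 / 3, abs=1e-12)
        assert res.df == 1

    def test_margins_preserved(self):
        res = chi_squared([[5, 9, 1], [3, 3, 7]])
        np.testing.assert_allclose(res.expected.sum(axis=0), res.observed.sum(axis=0))
        np.testing.assert_allclose(res.expected.sum(axis=1), res.observed.sum(axis=1))
        assert res.df == 2

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_squared([[0, 0], [1, 2]])

    @given(
        st.lists(
            st.lists(st.integers(0, 5), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_brute_force_oracle_small_tables(self, cells):
        """Σ(O−E)²/E computed by explicit loops matches on ≤3×3 tables."""
        obs = np.array(cells, dtype=float)
        if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
            return
        n = obs.sum()
        expected_chi2 = 0.0
        for i in range(3):
            for j in range(3):
                e = obs[i].sum() * obs[:, j].sum() / n
                expected_chi2 += (obs[i, j] - e) ** 2 / e
        assert chi_squared(obs).chi2 == pytest.approx(expected_chi2, abs=1e-9)


class TestReconstructCounts:
    def test_reference_sex_table(self):
        counts = reconstruct_counts(
            [(75.58, 17.45, 4.02, 2.96), (80.35, 12.80, 4.59, 2.25)],
            [1691, 1242],
        )
        np.testing.assert_array_equal(counts.sum(axis=0), [2276, 454, 125, 78])

    def test_simple_rows(self):
        np.testing.assert_array_equal(reconstruct_counts([(50, 50)], [10]), [[5, 5]])
        np.testing.assert_array_equal(
            reconstruct_counts([(33.33, 33.33, 33.33)], [3]), [[1, 1, 1]]
        )

    def test_reconciliation_failure_lists_residuals(self):
        # cells round to (0, 0, 0, 0) while the row n is 2
        with pytest.raises(ReconciliationError, match="-2"):
            reconstruct_counts([(25.0, 25.0, 25.0, 25.0)], [2])

    def test_bad_percent_sum(self):
        with pytest.raises(ValueError, match="sums to"):
            reconstruct_counts([(60.0, 30.0)], [10])


class TestPooledMean:
    def test_reference_wellbeing(self):
        value = pooled_mean((2276, 454, 125, 78), (50.48, 29.07, 45.50, 25.47))
        assert round(value, 2) == 46.29

    def test_trivial(self):
        assert pooled_mean([3, 7], [2.0, 2.0]) == pytest.approx(2.0)
        assert pooled_mean([1, 1], [0.0, 10.0]) == pytest.approx(5.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pooled_mean([1, 2], [1.0])


class TestAnovaFromSummary:
    def test_reference_distress(self):
        res = anova_from_summary(
            ref.GROUP_NS,
            ref.group_means("academic_distress"),
            ref.group_sds("academic_distress"),
        )
        assert round(res.eta2, 3) == 0.215
        assert res.df_between == 3 and res.df_within == 2929

    def test_reference_gpa(self):
        res = anova_from_summary(ref.GROUP_NS, ref.group_means("gpa"), ref.group_sds("gpa"))
        assert round(res.eta2, 3) == 0.033

    def test_hand_computed(self):
        # grand mean 0.5; SS_b = 2(0.5)² + 2(0.5)² = 1, MS_w = 1 ⇒ F = 1
        # (confirmed against scipy.stats.f_oneway on matching raw data)
        res = anova_from_summary([2, 2], [0.0, 1.0], [1.0, 1.0])
        assert res.F == pytest.approx(1.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            anova_from_summary([2, 2], [0.0], [1.0, 1.0])


class TestOnewayAnova:
    def test_identical_groups(self):
        y = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        res = oneway_anova(y, ["a"] * 3 + ["b"] * 3)
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.eta2 == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_summary_form(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=120)
        labels = rng.choice(["a", "b", "c", "d"], size=120)
        raw = oneway_anova(y, labels)
        ns, means, sds = [], [], []
        for g in pd.unique(labels):
            v = y[labels == g]
            ns.append(len(v)), means.append(v.mean()), sds.append(v.std(ddof=1))
        summ = anova_from_summary(ns, means, sds)
        assert raw.F == pytest.approx(summ.F, abs=1e-9)
        assert raw.eta2 == pytest.approx(summ.eta2, abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=90)
        labels = np.repeat(["a", "b", "c"], 30)
        res = oneway_anova(y, labels)
        F, p = sps.f_oneway(*(y[labels == g] for g in "abc"))
        assert res.F == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_posthoc_family(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=80)
        labels = np.repeat(["a", "b", "c", "d"], 20)
        res = oneway_anova(y, labels)
        assert len(res.posthoc) == 6
        for pc in res.posthoc:
            assert pc.p_adjusted >= pc.p_raw
            assert pc.p_adjusted <= 1.0
            assert pc.p_adjusted == pytest.approx(min(1.0, pc.p_raw * 6))

    def test_tiny_group_named(self):
        with pytest.raises(ValueError, match="'b'"):
            oneway_anova([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_monte_carlo_eta2_matches_reference(self):
        """Distress drawn at the reference group means/SDs and sizes gives
        η² near the published 0.215."""
        rng = np.random.default_rng(12)
        values, labels = [], []
        for g, n in enumerate(ref.GROUP_NS):
            m, s = ref.GROUP_SUMMARIES["academic_distress"][g]
            values.append(rng.normal(m, s, size=n))
            labels += [g] * n
        res = oneway_anova(np.concatenate(values), labels)
        assert res.eta2 == pytest.approx(0.215, abs=0.02)


class TestPearson:
    def test_perfect_and_antiperfect(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 5], "y": [-1.0, -2, -3, -5]})
        r, p = pearson_corr_matrix(df)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_fixed_example(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [2, 4, 7]})
        r, _ = pearson_corr_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(0.9934, abs=5e-5)

    def test_pairwise_complete_and_constant_flagged(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, np.nan], "y": [2.0, 4, 7, 8, 9], "c": [1.0, 1, 1, 1, 1]}
        )
        r, p = pearson_corr_matrix(df)
        assert np.isnan(r.loc["x", "c"])
        expected, _ = sps.pearsonr([1, 2, 3, 4], [2, 4, 7, 8])
        assert r.loc["x", "y"] == pytest.approx(expected, abs=1e-12)


class TestStandardize:
    def test_basic(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_moments(self):
        z = standardize(np.random.default_rng(0).normal(5, 3, size=50))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.random.default_rng(1).normal(size=30)
        np.testing.assert_allclose(standardize(3.5 * x - 2.0), standardize(x), atol=1e-12)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])
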
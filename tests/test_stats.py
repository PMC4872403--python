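"""Statistical procedures vs enumeration oracles and library cross-checks.

Each test statistic is validated two ways where possible: against a
brute-force enumeration of its exact small-sample null distribution, and
against an independent reference implementation (scipy / statsmodels /
pingouin) that is never used inside the package's own procedures.
"""

import itertools
import math
import warnings

import numpy as np
import pytest
import scipy.stats as sps

from ontrac.stats import (
    count_runs,
    friedman_test,
    hedges_effect_size,
    holm_adjust,
    kruskal_wallis,
    levene_test,
    mixed_anova,
    pearson_correlation,
    pooled_t_test,
    runs_test,
    wilcoxon_signed_rank,
)


class TestRunsTest:
    def test_perfect_interleaving_maximal_runs(self):
        res = runs_test([1, 3, 5], [2, 4, 6])
        assert res.statistic_value == 6

    def test_complete_separation_two_runs(self):
        res = runs_test([1, 2, 3], [10, 11, 12])
        assert res.statistic_value == 2

    def test_exact_p_matches_enumeration(self):
        """n=m=4: the exact p equals enumeration over all C(8,4) labelings."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            pooled = rng.permutation(np.arange(1, 9, dtype=float))
            a, b = pooled[:4], pooled[4:]
            res = runs_test(a, b)
            assert res.method_detail == "exact"
            order = np.argsort(np.concatenate([a, b]), kind="stable")
            # enumerate every assignment of 4 'A' labels to the 8 positions
            count = total = 0
            for positions in itertools.combinations(range(8), 4):
                labels = [0 if i in positions else 1 for i in range(8)]
                total += 1
                if count_runs(labels) <= res.statistic_value:
                    count += 1
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_normal_approximation_against_statsmodels(self):
        from statsmodels.sandbox.stats.runs import runstest_2samp

        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 12)
        res = runs_test(a, b)
        stat_sm, _ = runstest_2samp(a, b)
        # statsmodels returns the z statistic (continuity-corrected);
        # reconstruct ours and compare
        n, m = 15, 12
        mu = 2 * n * m / (n + m) + 1
        var = 2 * n * m * (2 * n * m - n - m) / ((n + m) ** 2 * (n + m - 1))
        z_ours = (res.statistic_value + 0.5 - mu) / math.sqrt(var)
        assert z_ours == pytest.approx(stat_sm, abs=1e-10)

    def test_ties_warn_and_still_run(self):
        with pytest.warns(UserWarning, match="tie"):
            res = runs_test([1, 2, 2, 3], [2, 4, 5, 6])
        assert 0 <= res.p_value <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            runs_test([], [1.0])


class TestFriedman:
    def test_consistent_ranking_hand_value(self):
        """Three blocks all ranked 1<2<3: column rank sums (3,6,9) give
        chi2_F = 12/(3*3*4)*(9+36+81) - 3*3*4 = 6."""
        res = friedman_test([[1, 5, 9], [2, 6, 10], [0, 4, 8]])
        assert res.statistic_value == pytest.approx(6.0)

    def test_fully_tied_matrix_degenerates_to_zero(self):
        res = friedman_test([[2, 2, 2], [7, 7, 7]])
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_statistic_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 3))
        res = friedman_test(x)
        # independent two-step oracle: scipy rankdata + the printed formula
        ranks = np.apply_along_axis(sps.rankdata, 1, x)
        n, k = x.shape
        oracle = 12.0 / (n * k * (k + 1)) * np.sum(ranks.sum(0) ** 2) - 3 * n * (k + 1)
        assert res.statistic_value == pytest.approx(oracle, abs=1e-12)
        stat_scipy, _ = sps.friedmanchisquare(*x.T)
        assert res.statistic_value == pytest.approx(stat_scipy, abs=1e-12)

    def test_exact_p_matches_permutation_enumeration(self):
        """3 blocks x 3 treatments, no ties: exact p equals enumeration over
        all (3!)^3 equally likely within-block rankings, with the statistic
        computed by scipy on each."""
        x = np.array([[1.0, 2.5, 2.0], [3.0, 1.0, 2.0], [1.5, 2.0, 3.0]])
        res = friedman_test(x)
        assert res.method_detail == "exact"
        obs, _ = sps.friedmanchisquare(*x.T)
        perms = list(itertools.permutations([1.0, 2.0, 3.0]))
        count = total = 0
        for combo in itertools.product(perms, repeat=3):
            stat, _ = sps.friedmanchisquare(*np.array(combo).T)
            total += 1
            if stat >= obs - 1e-12:
                count += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            friedman_test([[1, 2, np.nan], [3, 4, 5]])


class TestKruskalWallis:
    def test_hand_value_two_pairs(self):
        """Groups {1,2} and {3,4}: ranks 1-4, H = 2.4."""
        res = kruskal_wallis([[1, 2], [3, 4]])
        assert res.statistic_value == pytest.approx(2.4)

    def test_identical_groups_degenerate(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5]])
        assert res.statistic_value == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        groups = [rng.integers(0, 6, size=n).astype(float) for n in (8, 6, 7)]
        res = kruskal_wallis(groups)
        stat, p = sps.kruskal(*groups)
        assert res.statistic_value == pytest.approx(stat, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_two_group_equivalence_with_mann_whitney_z(self):
        """With two tie-free groups, H equals the squared standardized
        Mann-Whitney statistic."""
        rng = np.random.default_rng(4)
        pooled = rng.permutation(np.arange(1.0, 15.0))
        a, b = pooled[:8], pooled[8:]
        res = kruskal_wallis([a, b])
        u = sps.mannwhitneyu(a, b, method="asymptotic").statistic
        n, m = len(a), len(b)
        z = (u - n * m / 2) / math.sqrt(n * m * (n + m + 1) / 12.0)
        assert res.statistic_value == pytest.approx(z * z, abs=1e-10)


class TestWilcoxon:
    def test_uniform_shift_n6_exact_tail(self):
        """post = pre + c: W+ is maximal and the exact two-sided p is 2/64."""
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        post = [x + 2.0 for x in pre]
        res = wilcoxon_signed_rank(pre, post)
        assert res.statistic_value == 21.0
        assert res.p_value == pytest.approx(2 / 64)

    def test_antisymmetric_differences_center_null(self):
        pre = [0.0, 0.0, 0.0, 0.0]
        post = [1.0, -1.0, 2.0, -2.0]
        res = wilcoxon_signed_rank(pre, post)
        assert res.statistic_value == pytest.approx(4 * 5 / 4)  # null mean
        assert res.p_value == 1.0

    def test_exact_p_matches_sign_pattern_enumeration(self):
        """n=10 random pairs: exact p equals the full 2^10 enumeration."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            d = rng.integers(1, 8, size=10) * rng.choice([-1.0, 1.0], size=10)
            res = wilcoxon_signed_rank(np.zeros(10), d)
            ranks = sps.rankdata(np.abs(d))
            w_obs = ranks[d > 0].sum()
            ws = [
                np.sum(ranks[np.array(signs, dtype=bool)])
                for signs in itertools.product([0, 1], repeat=10)
            ]
            ws = np.array(ws)
            p_oracle = min(1.0, 2 * min(np.mean(ws <= w_obs), np.mean(ws >= w_obs)))
            assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_scipy_exact_mode(self):
        rng = np.random.default_rng(6)
        pre = rng.normal(size=12)
        post = pre + rng.normal(0.4, 1.0, size=12)
        res = wilcoxon_signed_rank(pre, post)
        ref = sps.wilcoxon(post - pre, mode="exact")
        # scipy reports min(W+, W-); same p-value
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_zero_differences_flagged(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.method_detail == "degenerate"
        assert math.isnan(res.statistic_value)

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4], [1, 2, 5, 7])
        ref = sps.wilcoxon([0, 0, 2, 3], mode="exact", zero_method="wilcox")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestLevene:
    def test_identical_spread_patterns_zero(self):
        res = levene_test([[1.0, 2.0, 3.0], [11.0, 12.0, 13.0]])
        assert res.statistic_value == pytest.approx(0.0)

    def test_matches_scipy_mean_centered(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0, s, size=n) for s, n in ((1, 9), (2.5, 7), (1.5, 8))]
        res = levene_test(groups)
        stat, p = sps.levene(*groups, center="mean")
        assert res.statistic_value == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_compositional_oracle_deviations_then_anova(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(size=6), rng.normal(0, 3, size=8)]
        res = levene_test(groups)
        z = [np.abs(g - g.mean()) for g in groups]
        stat, p = sps.f_oneway(*z)
        assert res.statistic_value == pytest.approx(stat, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_inflating_one_group_increases_statistic(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        stats = [
            levene_test([a, b * scale]).statistic_value for scale in (2.0, 4.0, 8.0)
        ]
        assert stats[0] < stats[1] < stats[2]


class TestMixedAnova:
    @staticmethod
    def _data(n1=11, n2=7, m=5, seed=10, effect=0.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n1 + n2, m))
        x[:n1] += effect
        labels = ["a"] * n1 + ["b"] * n2
        return x, labels

    def test_df_structure_at_study_sizes(self):
        """11 completers vs 7 controls on 5 measures: arm df (1,16),
        interaction df (4,64)."""
        x, labels = self._data()
        res = mixed_anova(x, labels)
        assert res["arm"].df == (1, 16)
        assert res["arm_x_measure"].df == (4, 64)

    def test_location_invariance(self):
        x, labels = self._data(seed=11)
        base = mixed_anova(x, labels)
        shifted = mixed_anova(x + 137.0, labels)
        for key in base:
            assert shifted[key].statistic_value == pytest.approx(
                base[key].statistic_value, abs=1e-9
            )

    def test_null_arm_f_calibrated(self):
        """Randomly permuted labels with no effect: the arm F averages to
        its null expectation df2/(df2-2) and rejects at ~alpha."""
        rng = np.random.default_rng(12)
        fs = []
        rejects = 0
        for _ in range(500):
            x = rng.normal(size=(18, 5))
            labels = rng.permutation(["a"] * 11 + ["b"] * 7)
            res = mixed_anova(x, labels)["arm"]
            fs.append(res.statistic_value)
            rejects += res.p_value <= 0.05
        assert np.mean(fs) == pytest.approx(16 / 14, abs=0.15)
        assert rejects / 500 <= 0.08

    def test_matches_pingouin_mixed_anova(self):
        import pandas as pd
        import pingouin as pg

        x, labels = self._data(seed=13, effect=0.4)
        rows = [
            {"subject": i, "arm": labels[i], "measure": f"m{j}", "value": x[i, j]}
            for i in range(x.shape[0])
            for j in range(x.shape[1])
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pg.mixed_anova(
                pd.DataFrame(rows),
                dv="value",
                within="measure",
                between="arm",
                subject="subject",
            ).set_index("Source")
        res = mixed_anova(x, labels)
        assert res["arm"].statistic_value == pytest.approx(
            float(ref.loc["arm", "F"]), rel=1e-9
        )
        assert res["arm_x_measure"].statistic_value == pytest.approx(
            float(ref.loc["Interaction", "F"]), rel=1e-9
        )
        assert res["arm"].p_value == pytest.approx(float(ref.loc["arm", "p_unc"]), rel=1e-9)

    def test_missing_cells_rejected(self):
        x, labels = self._data()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(x, labels)


class TestEffectSizesAndCorrelation:
    def test_correction_factor_at_study_sizes(self):
        """n1=11, n2=7: J = 1 - 3/(4*18-9) = 1 - 3/63."""
        rng = np.random.default_rng(14)
        es = hedges_effect_size(rng.normal(1, 1, 11), rng.normal(0, 1, 7))
        assert es.correction_j == pytest.approx(1 - 3 / 63, abs=1e-15)
        assert es.hedges_g == pytest.approx(es.cohen_d * es.correction_j, abs=1e-15)
        assert abs(es.hedges_g) <= abs(es.cohen_d)

    def test_identical_groups_zero_effect(self):
        es = hedges_effect_size([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert es.cohen_d == pytest.approx(0.0)
        assert es.hedges_g == pytest.approx(0.0)

    def test_formula_matches_independent_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            a = rng.normal(0.3, 1.2, size=int(rng.integers(2, 15)))
            b = rng.normal(0.0, 0.8, size=int(rng.integers(2, 15)))
            es = hedges_effect_size(a, b)
            n1, n2 = len(a), len(b)
            sp = math.sqrt(
                ((n1 - 1) * a.std(ddof=1) ** 2 + (n2 - 1) * b.std(ddof=1) ** 2)
                / (n1 + n2 - 2)
            )
            d = (a.mean() - b.mean()) / sp
            g = d * (1 - 3 / (4 * (n1 + n2) - 9))
            assert es.hedges_g == pytest.approx(g, abs=1e-12)

    def test_correction_vanishes_for_large_samples(self):
        rng = np.random.default_rng(16)
        es = hedges_effect_size(rng.normal(size=500), rng.normal(size=500))
        assert es.correction_j > 0.999

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_effect_size([1.0, 1.0], [1.0, 1.0])

    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_correlation(x, x).statistic_value == 1.0
        assert pearson_correlation(x, [-v for v in x]).statistic_value == -1.0

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=11)
        y = 0.6 * x + rng.normal(size=11)
        res = pearson_correlation(x, y)
        ref = sps.pearsonr(x, y)
        assert res.statistic_value == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_pooled_t_matches_scipy(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(0.5, 1, 11), rng.normal(0, 1, 7)
        res = pooled_t_test(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic_value == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestInvariances:
    def test_rank_tests_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=(5, 3))
        groups = [rng.normal(size=7), rng.normal(1, 1, size=6)]

        def transform(v):
            return np.exp(v) + v**3

        assert friedman_test(x).statistic_value == pytest.approx(
            friedman_test(transform(x)).statistic_value, abs=1e-12
        )
        assert kruskal_wallis(groups).statistic_value == pytest.approx(
            kruskal_wallis([transform(g) for g in groups]).statistic_value, abs=1e-12
        )
        assert runs_test(*groups).statistic_value == runs_test(
            *[transform(g) for g in groups]
        ).statistic_value

    def test_subject_relabeling_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(size=8), rng.normal(size=8)
        # statistics depend only on values, not on any subject identity:
        # permuting within-sample order changes nothing
        perm = rng.permutation(8)
        assert runs_test(a, b).p_value == runs_test(a[perm], b[perm]).p_value
        assert kruskal_wallis([a, b]).statistic_value == pytest.approx(
            kruskal_wallis([a[perm], b[perm]]).statistic_value
        )

    def test_holm_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.001, 0.02, 0.04, 0.2, 0.5]
        ours = holm_adjust(p)
        _, ref, _, _ = multipletests(p, method="holm")
        assert np.allclose(ours, ref)
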
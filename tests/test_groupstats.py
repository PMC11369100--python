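"""Statistical machinery validated against hand oracles and libraries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import oracle_dunn_z, oracle_kruskal, oracle_levene
from cogsubtype import (
    adjust_pvalues,
    chi2_independence,
    kruskal_dunn,
    levene_homogeneity,
    partial_correlation_matrix,
    ranked_anova_interaction,
    subject_correlation_blocks,
    welch_anova,
)


# ---------------------------------------------------------------------------
# subject correlation blocks
# ---------------------------------------------------------------------------

class TestCorrelationBlocks:
    def _cohort(self, rng, sizes=(56, 52, 118), n_vars=6):
        groups = (
            ["control"] * sizes[0]
            + ["affective"] * sizes[1]
            + ["non-affective"] * sizes[2]
        )
        X = rng.normal(size=(sum(sizes), n_vars))
        return pd.DataFrame(X), groups

    def test_block_t_degrees_of_freedom_from_full_squares(self, rng):
        """Full square blocks: df = n_a^2 + n_b^2 - 2 for each group pair."""
        X, groups = self._cohort(rng)
        res = subject_correlation_blocks(X, groups)
        assert res.block_t[("control", "affective")].df == 56**2 + 52**2 - 2 == 5838
        assert res.block_t[("control", "non-affective")].df == 56**2 + 118**2 - 2 == 17058
        assert res.block_t[("affective", "non-affective")].df == 52**2 + 118**2 - 2 == 16626

    def test_levene_dfs_match_subject_counts(self, rng):
        X, groups = self._cohort(rng)
        res = subject_correlation_blocks(X, groups)
        assert res.levene[("affective", "non-affective")].df2 == 52 + 118 - 2 == 168
        assert res.levene[("control", "affective")].df2 == 56 + 52 - 2 == 106

    def test_two_by_two_within_block_mean_includes_diagonal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 5))
        groups = ["control", "control", "affective", "affective"]
        res = subject_correlation_blocks(pd.DataFrame(X), groups)
        r = np.corrcoef(X[0], X[1])[0, 1]
        assert res.block_means[("control", "control")] == pytest.approx((2 + 2 * r) / 4)

    def test_identical_profiles_give_unit_within_block(self):
        profile_a = np.array([1.0, 2.0, 5.0, 3.0])
        profile_b = np.array([0.0, 4.0, 1.0, 2.0])
        X = pd.DataFrame([profile_a, profile_a, profile_b, profile_b])
        groups = ["control", "control", "affective", "affective"]
        res = subject_correlation_blocks(X, groups)
        assert res.block_means[("control", "control")] == pytest.approx(1.0)
        assert res.block_means[("affective", "affective")] == pytest.approx(1.0)

    def test_more_homogeneous_group_detected(self, rng):
        n = 40
        common = rng.normal(size=10)
        tight = common + 0.2 * rng.normal(size=(n, 10))
        loose = common + 2.0 * rng.normal(size=(n, 10))
        X = pd.DataFrame(np.vstack([tight, loose]))
        groups = ["control"] * n + ["non-affective"] * n
        res = subject_correlation_blocks(X, groups)
        assert (
            res.block_means[("control", "control")]
            > res.block_means[("non-affective", "non-affective")]
        )
        rep = res.levene[("control", "non-affective")]
        assert rep.p_value < 0.01

    def test_constant_profile_rejected(self):
        X = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 2.0, 1.0]])
        with pytest.raises(ValueError, match="constant"):
            subject_correlation_blocks(X, ["control", "affective"])


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

class TestKruskalDunn:
    def test_matches_brute_force_oracle(self):
        samples = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        values = np.concatenate(samples)
        labels = np.repeat(["a", "b", "c"], 3)
        rep = kruskal_dunn(values, labels)
        assert rep.statistic == pytest.approx(oracle_kruskal(samples), abs=1e-10)
        h_scipy, p_scipy = stats.kruskal(*samples)
        assert rep.statistic == pytest.approx(h_scipy, abs=1e-10)
        assert rep.p_value == pytest.approx(p_scipy, abs=1e-10)

    def test_matches_oracle_with_ties(self):
        samples = [np.array([1.0, 2, 2, 3]), np.array([2.0, 3, 3]), np.array([1.0, 4])]
        values = np.concatenate(samples)
        labels = np.repeat(["a", "b", "c"], [4, 3, 2])
        rep = kruskal_dunn(values, labels)
        assert rep.statistic == pytest.approx(oracle_kruskal(samples), abs=1e-10)
        h_scipy, _ = stats.kruskal(*samples)
        assert rep.statistic == pytest.approx(h_scipy, abs=1e-10)

    def test_identical_groups_give_zero_h(self):
        values = np.array([1.0, 2, 3, 1, 2, 3])
        labels = np.repeat(["a", "b"], 3)
        rep = kruskal_dunn(values, labels)
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0)

    def test_dunn_z_and_bonferroni(self):
        samples = [np.array([1.0, 2, 3, 4]), np.array([5.0, 6, 7]), np.array([8.0, 9, 10, 11])]
        values = np.concatenate(samples)
        labels = np.repeat(["a", "b", "c"], [4, 3, 4])
        rep = kruskal_dunn(values, labels)
        assert len(rep.posthoc) == 3  # C(3, 2)
        for (i, j), key in [((0, 1), ("a", "b")), ((0, 2), ("a", "c")), ((1, 2), ("b", "c"))]:
            ph = rep.posthoc[key]
            assert ph["statistic"] == pytest.approx(oracle_dunn_z(samples, i, j), abs=1e-10)
            assert ph["p_corrected"] == pytest.approx(min(1.0, ph["p_raw"] * 3), abs=1e-12)
            assert ph["p_corrected"] >= ph["p_raw"]

    def test_monotone_transform_invariance(self, rng):
        values = rng.normal(size=30)
        labels = rng.choice(["a", "b", "c"], 30)
        r1 = kruskal_dunn(values, labels)
        r2 = kruskal_dunn(np.exp(values), labels)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn([1.0, 2.0], ["a", "a"])


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

class TestChi2:
    def test_gender_table_reconstruction(self):
        """Female percentages 33.9/57.7/30.5 of 56/52/118 -> chi2 ~ 11.78."""
        sizes = np.array([56, 52, 118])
        female = np.round(np.array([0.339, 0.577, 0.305]) * sizes).astype(int)
        table = np.vstack([female, sizes - female])
        rep = chi2_independence(table)
        assert rep.df == 2
        assert rep.statistic == pytest.approx(11.78, abs=0.05)

    def test_matches_scipy_and_hand_arithmetic(self):
        table = np.array([[10.0, 20.0], [30.0, 5.0]])
        rep = chi2_independence(table)
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        assert rep.statistic == pytest.approx(chi2, abs=1e-10)
        assert rep.p_value == pytest.approx(p, abs=1e-10)
        # hand: expected = outer(margins)/N
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        assert rep.statistic == pytest.approx(hand, abs=1e-10)

    def test_independent_table_gives_zero(self):
        table = np.outer([10, 20, 30], [5, 15])
        rep = chi2_independence(table)
        assert rep.statistic == pytest.approx(0.0, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_independence([[0, 0], [1, 2]])


# ---------------------------------------------------------------------------
# Levene
# ---------------------------------------------------------------------------

class TestLevene:
    def test_matches_hand_oracle_and_scipy(self):
        samples = [np.array([1.0, 3, 5]), np.array([2.0, 2, 8])]
        rep = levene_homogeneity({"a": samples[0], "b": samples[1]})
        assert rep.statistic == pytest.approx(oracle_levene(samples), abs=1e-10)
        w, p = stats.levene(*samples, center="mean")
        assert rep.statistic == pytest.approx(w, abs=1e-10)
        assert rep.p_value == pytest.approx(p, abs=1e-10)
        assert (rep.df, rep.df2) == (1, 4)

    def test_identical_groups_give_zero(self):
        rep = levene_homogeneity({"a": [1.0, 2, 3], "b": [1.0, 2, 3]})
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            levene_homogeneity({"a": [1.0], "b": [1.0, 2.0]})


# ---------------------------------------------------------------------------
# ranked ANOVA
# ---------------------------------------------------------------------------

class TestRankedAnova:
    def _data(self, rng, n_per=10, n_net=4, effects=None):
        groups = ["controls", "cluster0", "cluster1", "cluster2"]
        rows, labels = [], []
        for gi, g in enumerate(groups):
            block = rng.normal(size=(n_per, n_net))
            if effects is not None:
                block += effects[gi]
            rows.append(block)
            labels += [g] * n_per
        return pd.DataFrame(np.vstack(rows)), labels

    def test_interaction_f_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        vols, labels = self._data(rng)
        rep = ranked_anova_interaction(vols, labels, alpha=1e-12)
        n, p = vols.shape
        long = pd.DataFrame(
            {
                "rank": stats.rankdata(vols.to_numpy().ravel()),
                "group": np.repeat(labels, p),
                "network": np.tile([f"n{j}" for j in range(p)], n),
            }
        )
        fit = smf.ols("rank ~ C(group) * C(network)", data=long).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        f_sm = tab.loc["C(group):C(network)", "F"]
        assert rep.statistic == pytest.approx(f_sm, rel=1e-8)
        assert rep.df == (4 - 1) * (p - 1)
        assert rep.statistic >= 0.0

    def test_null_type_one_error_calibrated(self):
        rejections = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            vols, labels = self._data(rng, n_per=8, n_net=3)
            rep = ranked_anova_interaction(vols, labels, alpha=1e-12)
            rejections += rep.p_value < 0.05
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, 0.05)
        assert lo <= rejections <= hi

    def test_planted_network_effects_flagged_posthoc(self, rng):
        # group effects concentrated in the first 2 of 8 networks
        effects = []
        for gi in range(4):
            e = np.zeros(8)
            e[:2] = -1.5 * gi
            effects.append(e)
        vols, labels = self._data(rng, n_per=30, n_net=8, effects=effects)
        rep = ranked_anova_interaction(vols, labels)
        assert rep.p_value < 0.001
        flagged = {k for k, v in rep.posthoc.items() if v["significant"]}
        assert flagged == {0, 1}

    def test_welch_anova_matches_pingouin(self, rng):
        import pingouin as pg

        data = {g: rng.normal(loc=i, scale=1 + i, size=12 + i)
                for i, g in enumerate("abcd")}
        rep = welch_anova(data)
        long = pd.DataFrame(
            {"y": np.concatenate(list(data.values())),
             "g": np.repeat(list(data), [len(v) for v in data.values()])}
        )
        tab = pg.welch_anova(data=long, dv="y", between="g")
        assert rep.statistic == pytest.approx(float(tab["F"].iloc[0]), rel=1e-8)
        assert rep.df2 == pytest.approx(float(tab["ddof2"].iloc[0]), rel=1e-8)
        assert rep.p_value == pytest.approx(float(tab["p_unc"].iloc[0]), rel=1e-6)


# ---------------------------------------------------------------------------
# partial correlation
# ---------------------------------------------------------------------------

class TestPartialCorrelation:
    def test_residual_method_equals_recursion_formula(self, rng):
        n = 40
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.3 * z + rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y})
        res = partial_correlation_matrix(df, pd.DataFrame({"z": z}))
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        recursion = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        got = res.pairs.loc[0, "partial_r"]
        assert got == pytest.approx(recursion, abs=1e-10)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        n = 50
        data = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "z"])
        res = partial_correlation_matrix(data[["x", "y"]], data[["z"]])
        tab = pg.partial_corr(data=data, x="x", y="y", covar="z")
        assert res.pairs.loc[0, "partial_r"] == pytest.approx(
            float(tab["r"].iloc[0]), abs=1e-10
        )
        assert res.pairs.loc[0, "p_raw"] == pytest.approx(
            float(tab["p_val"].iloc[0]), abs=1e-8
        )

    def test_trivariate_closed_form_recovered(self):
        # population correlations r_xy=0.6, r_xz=0.5, r_yz=0.5
        # -> partial r_xy.z = (0.6 - 0.25) / 0.75 = 0.4667
        cov = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.5], [0.5, 0.5, 1.0]])
        rng = np.random.default_rng(99)
        sample = rng.multivariate_normal(np.zeros(3), cov, size=10_000)
        df = pd.DataFrame(sample, columns=["x", "y", "z"])
        res = partial_correlation_matrix(df[["x", "y"]], df[["z"]])
        assert res.pairs.loc[0, "partial_r"] == pytest.approx(0.35 / 0.75, abs=0.03)

    def test_empty_covariates_equal_plain_pearson(self, rng):
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        res = partial_correlation_matrix(df, None)
        for _, row in res.pairs.iterrows():
            r, p = stats.pearsonr(df[row["var_a"]], df[row["var_b"]])
            assert row["partial_r"] == pytest.approx(r, abs=1e-12)
            assert row["p_raw"] == pytest.approx(p, abs=1e-10)

    def test_uncorrelated_covariate_leaves_r_nearly_unchanged(self, rng):
        n = 5000
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=n)  # independent of both
        res = partial_correlation_matrix(
            pd.DataFrame({"x": x, "y": y}), pd.DataFrame({"z": z})
        )
        raw = np.corrcoef(x, y)[0, 1]
        assert res.pairs.loc[0, "partial_r"] == pytest.approx(raw, abs=0.02)

    def test_symmetry_and_bounds(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        df.columns = list("abcd")
        res = partial_correlation_matrix(df, None)
        mat = res.matrix()
        assert np.allclose(mat, mat.T)
        assert (mat.to_numpy() <= 1.0 + 1e-12).all()
        assert (mat.to_numpy() >= -1.0 - 1e-12).all()

    def test_sample_size_validation(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 2)), columns=["a", "b"])
        cov = pd.DataFrame(rng.normal(size=(4, 2)), columns=["c", "d"])
        with pytest.raises(ValueError, match="covariates"):
            partial_correlation_matrix(df, cov)


# ---------------------------------------------------------------------------
# p-value adjustment
# ---------------------------------------------------------------------------

class TestAdjustPvalues:
    @pytest.mark.parametrize("method", ["bonferroni", "holm", "fdr_bh"])
    def test_matches_statsmodels(self, rng, method):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(15)
        got = adjust_pvalues(p, method)
        _, expected, _, _ = multipletests(p, method=method)
        assert np.allclose(got, expected, atol=1e-12)

    def test_corrected_never_below_raw(self, rng):
        p = rng.random(10)
        for method in ("bonferroni", "holm", "fdr_bh"):
            assert (adjust_pvalues(p, method) >= p - 1e-15).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues(np.array([0.5]), "weird")
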
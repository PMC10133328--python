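"""Statistical engine: routing, omnibus tests, post-hocs, correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vallescape.stats import (
    anova_tukey,
    compare_groups,
    dunn_posthoc,
    kruskal_wallis,
    route_test,
    significance_letters,
    spearman_correlogram,
)


class TestRouting:
    def test_skewed_groups_route_nonparametric(self):
        rng = np.random.default_rng(1)
        groups = {g: np.exp(rng.normal(0, 1.5, 30)) for g in "abc"}
        assert route_test(groups) == "nonparametric"

    def test_gaussian_groups_route_parametric_most_seeds(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            groups = {g: rng.normal(0, 1, 30) for g in "abc"}
            hits += route_test(groups) == "parametric"
        assert hits >= 45  # >= 90% under the Gaussian equal-variance null

    def test_matches_independent_reimplementation(self):
        """Cross-check routing components: Bartlett against the explicit
        chi-square formula, Shapiro-Wilk against an independent wrapper."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        cases = [
            {g: rng.normal(0, 1, 12) for g in "ab"},
            {g: rng.normal(0, 1 + i, 10) for i, g in enumerate("abc")},
            {g: np.exp(rng.normal(0, 1, 15)) for g in "abc"},
            {g: rng.uniform(0, 1, 20) for g in "abcd"},
            {g: rng.normal(5, 0.1, 8) for g in "ab"},
        ]
        for groups in cases:
            vals = list(groups.values())
            # Bartlett by hand
            k = len(vals)
            n_i = np.array([len(v) for v in vals])
            s2_i = np.array([np.var(v, ddof=1) for v in vals])
            n = n_i.sum()
            sp2 = ((n_i - 1) * s2_i).sum() / (n - k)
            stat = ((n - k) * math.log(sp2) - ((n_i - 1) * np.log(s2_i)).sum()) / (
                1 + (sum(1 / (n_i - 1)) - 1 / (n - k)) / (3 * (k - 1))
            )
            p_bartlett = sps.chi2.sf(stat, k - 1)
            residuals = np.concatenate([v - v.mean() for v in vals])
            p_shapiro = float(pingouin.normality(residuals)["pval"].iloc[0])
            expected = "parametric" if (p_shapiro > 0.05 and p_bartlett > 0.05) else "nonparametric"
            assert route_test(groups) == expected

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            route_test({"a": [1, 2], "b": [1, 2, 3]})


class TestKruskalWallis:
    def test_hand_ranked_three_groups(self):
        # ranks 1..9 split consecutively: H = 12/(9*10) * (12+75+192)*3/3 - 30 = 7.2
        h, p = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_invariant_under_monotone_transform(self, rng):
        groups = {g: rng.random(10) * 10 for g in "abc"}
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis({g: np.exp(v) for g, v in groups.items()})
        assert h1 == pytest.approx(h2)

    def test_degenerate_identical_values_flagged(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis({"a": [1, 1, 1], "b": [1, 1, 1]})

    def test_null_rejection_rate_calibrated(self):
        """Type-I error of the routed workflow at alpha=0.05, Gaussian and
        lognormal nulls; expected in [0.03, 0.07] per the chi-square
        approximation."""
        for transform in (lambda x: x, np.exp):
            rng = np.random.default_rng(123)
            rejections = 0
            reps = 5000
            for _ in range(reps):
                data = transform(rng.normal(0, 1, (3, 10)))
                groups = {g: data[i] for i, g in enumerate("abc")}
                _, p = kruskal_wallis(groups)
                rejections += p < 0.05
            assert 0.03 <= rejections / reps <= 0.07


class TestDunn:
    def test_identical_groups_z_zero(self):
        table = dunn_posthoc({"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [10.0, 11, 12]})
        row = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0]
        assert row.z == pytest.approx(0.0)
        assert row.p == pytest.approx(1.0)

    def test_matches_hand_rank_formula(self):
        # groups (1,2,3),(4,5,6),(7,8,9): mean ranks 2, 5, 8; no ties;
        # se = sqrt(9*10/12 * 2/3) = sqrt(5)
        table = dunn_posthoc({"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]})
        z_ab = table[(table.group1 == "a") & (table.group2 == "b")].iloc[0].z
        z_ac = table[(table.group1 == "a") & (table.group2 == "c")].iloc[0].z
        assert z_ab == pytest.approx(-3 / math.sqrt(5))
        assert z_ac == pytest.approx(-6 / math.sqrt(5))
        p_ab = 2 * sps.norm.sf(3 / math.sqrt(5))
        assert table[(table.group1 == "a") & (table.group2 == "b")].iloc[0].p == pytest.approx(p_ab)

    def test_tie_correction_enters_variance(self):
        # with ties the pooled-rank variance shrinks by sum(t^3-t)/(12(N-1))
        groups = {"a": [1.0, 1.0, 2.0], "b": [3.0, 4.0, 5.0]}
        pooled = np.concatenate(list(groups.values()))
        ranks = sps.rankdata(pooled)
        tie_term = (2**3 - 2) / (12 * (len(pooled) - 1))
        var = len(pooled) * (len(pooled) + 1) / 12 - tie_term
        se = math.sqrt(var * (2 / 3))
        expected_z = (ranks[:3].mean() - ranks[3:].mean()) / se
        table = dunn_posthoc(groups)
        assert table.iloc[0].z == pytest.approx(expected_z)

    def test_shares_pooled_ranking_with_kruskal(self, rng):
        """Dunn z's and the KW statistic must come from one ranking: with two
        groups, H equals z^2 up to the chi-square/normal equivalence."""
        groups = {"a": rng.random(8), "b": rng.random(8)}
        h, _ = kruskal_wallis(groups)
        z = dunn_posthoc(groups).iloc[0].z
        assert h == pytest.approx(z**2)

    def test_holm_adjustment_monotone(self, rng):
        groups = {g: rng.random(6) for g in "abcde"}
        none = dunn_posthoc(groups, adjustment="none")
        holm = dunn_posthoc(groups, adjustment="holm")
        assert (holm.p_adjusted >= none.p_adjusted - 1e-12).all()
        assert len(none) == 10  # all unordered pairs of 5 groups

    def test_unknown_adjustment_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc({"a": [1, 2], "b": [3, 4]}, adjustment="sidak")


class TestAnovaTukey:
    def test_two_group_f_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f, p_f, _ = anova_tukey({"a": a, "b": b})
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_matches_sum_of_squares_oracle(self):
        groups = {"a": [1.0, 2, 3], "b": [2.0, 4, 6], "c": [5.0, 5, 8]}
        f, _, _ = anova_tukey(groups)
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        expected = (ss_between / 2) / (ss_within / (len(all_vals) - 3))
        assert f == pytest.approx(expected)

    def test_degenerate_flagged(self):
        with pytest.raises(ValueError, match="identical"):
            anova_tukey({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]})

    def test_pairwise_covers_all_pairs(self, rng):
        groups = {g: rng.normal(0, 1, 5) for g in "abcd"}
        _, _, pairwise = anova_tukey(groups)
        assert len(pairwise) == 6


class TestSignificanceLetters:
    def test_no_pair_significant(self):
        table = pd.DataFrame(
            {"group1": ["F", "F"], "group2": ["R", "N"], "p_adjusted": [0.4, 0.9]}
        )
        annot = significance_letters(table)
        assert all(not s for s in annot.values())

    def test_single_significant_pair_symmetric(self):
        table = pd.DataFrame(
            {"group1": ["F", "F", "R"], "group2": ["R", "N", "N"],
             "p_adjusted": [0.01, 0.2, 0.8]}
        )
        annot = significance_letters(table)
        assert annot == {"F": {"R"}, "R": {"F"}, "N": set()}

    def test_matches_threshold_oracle(self, rng):
        import itertools

        groups = list("FMHRN")
        rows = [
            {"group1": a, "group2": b, "p_adjusted": rng.random()}
            for a, b in itertools.combinations(groups, 2)
        ]
        table = pd.DataFrame(rows)
        annot = significance_letters(table, alpha=0.5)
        for row in rows:
            assert (row["group2"] in annot[row["group1"]]) == (row["p_adjusted"] < 0.5)


class TestSpearman:
    def test_monotone_relationships(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        df["up"] = np.exp(df.x)
        df["down"] = -df.x**3
        rho, _ = spearman_correlogram(df)
        assert rho.at["x", "up"] == pytest.approx(1.0)
        assert rho.at["x", "down"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho, rho.T)

    def test_matches_rank_then_pearson_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 7.0])
        y = rng.random(8)
        rho, _ = spearman_correlogram(pd.DataFrame({"x": x, "y": y}))
        expected = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho.at["x", "y"] == pytest.approx(expected)

    def test_pairwise_complete_exclusion(self, rng):
        df = pd.DataFrame({"x": rng.random(8), "y": rng.random(8)})
        df.loc[2, "y"] = np.nan
        rho, _ = spearman_correlogram(df)
        sub = df.dropna()
        expected = sps.spearmanr(sub.x, sub.y).statistic
        assert rho.at["x", "y"] == pytest.approx(expected)

    def test_too_few_units_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 1, 3]})
        with pytest.raises(ValueError, match="<4"):
            spearman_correlogram(df)


def test_routed_workflow_end_to_end(rng):
    groups = {g: rng.normal(i, 1, 12) for i, g in enumerate("FMHRN")}
    res = compare_groups("demo", groups)
    assert res.routing in ("parametric", "nonparametric")
    assert len(res.pairwise) == 10
    assert set(res.annotations) == set("FMHRN")
    sig = res.pairwise[res.pairwise.p_adjusted < 0.05]
    for _, row in sig.iterrows():
        assert row.group2 in res.annotations[row.group1]
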
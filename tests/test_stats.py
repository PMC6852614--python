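import numpy as np
import pandas as pd
import pytest
import scipy.stats

from phnatlas import stats


class TestPearson:
    def test_perfect_line_gives_r_one(self):
        x = np.arange(10.0)
        r, p, n = stats.pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_five_point_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 6.0, 9.0])
        r, p, n = stats.pearson_test(x, y)
        # independent oracle: the raw covariance formula
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, rel=1e-12)
        t = expected * np.sqrt((n - 2) / (1 - expected**2))
        assert p == pytest.approx(2 * scipy.stats.t.sf(abs(t), n - 2), rel=1e-9)

    def test_incomplete_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        _, _, n = stats.pearson_test(x, y)
        assert n == 3

    def test_zero_variance_rejected(self):
        with pytest.raises(stats.DegenerateInputError, match="degenerate"):
            stats.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLoglogFit:
    def test_noiseless_recovery_to_machine_precision(self):
        pi = np.logspace(-2, 0, 20)
        percent = 10 ** (-0.5 - 1.2 * np.log10(pi))
        fit = stats.loglog_fit(percent, pi)
        assert fit.slope == pytest.approx(-1.2, abs=1e-12)
        assert fit.intercept == pytest.approx(-0.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.zero_dropped == 0

    def test_zeros_dropped_and_counted(self):
        pi = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        percent = np.array([1.0, 0.0, 2.0, 3.0, np.nan])
        fit = stats.loglog_fit(percent, pi)
        assert fit.n == 3
        assert fit.zero_dropped == 2

    def test_all_zero_percent_raises_with_count(self):
        with pytest.raises(stats.DegenerateInputError, match="zero_dropped=4"):
            stats.loglog_fit([0.0, 0.0, 0.0, 0.0], [0.1, 0.2, 0.3, 0.4])

    def test_matches_closed_form_ols_on_four_points(self):
        pi = np.array([0.05, 0.1, 0.4, 0.9])
        percent = np.array([8.0, 3.0, 1.5, 0.4])
        fit = stats.loglog_fit(percent, pi)
        x, y = np.log10(pi), np.log10(percent)
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        se = np.sqrt((resid**2).sum() / (len(x) - 2) / sxx)
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        assert fit.se_slope == pytest.approx(se, rel=1e-12)

    def test_slope_recovery_under_noise(self):
        rng = np.random.default_rng(10)
        slopes = []
        for _ in range(200):
            x = rng.uniform(-2, 0, 100)
            y = -0.5 - 1.0 * x + rng.normal(0, 0.2, 100)
            fit = stats.loglog_fit(10**y, 10**x)
            slopes.append(fit.slope)
        mean = np.mean(slopes)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(mean - (-1.0)) < 3 * se


class TestSlopeDifference:
    def test_identical_fits_give_zero(self):
        fit = stats.RegressionResult(-1.0, 0.0, 0.1, 0.9, 0.001, 50, 0)
        z, p = stats.slope_difference_z(fit, fit)
        assert z == 0.0 and p == 1.0

    def test_hand_arithmetic(self):
        f1 = stats.RegressionResult(-1.0, 0.0, 0.1, 0.9, 0.001, 50, 0)
        f2 = stats.RegressionResult(-1.5, 0.0, 0.1, 0.9, 0.001, 50, 0)
        z, p = stats.slope_difference_z(f1, f2)
        assert z == pytest.approx(0.5 / np.sqrt(0.02), rel=1e-12)
        assert z == pytest.approx(3.5355, abs=1e-4)

    def test_missing_se_rejected(self):
        f1 = stats.RegressionResult(-1.0, 0.0, float("nan"), 0.9, 0.001, 50, 0)
        with pytest.raises(ValueError, match="standard error"):
            stats.slope_difference_z(f1, f1)


class TestRegionPiModel:
    def test_single_region_reduces_to_loglog_fit(self):
        rng = np.random.default_rng(11)
        pi = 10 ** rng.uniform(-2, 0, 30)
        percent = 10 ** (-0.5 - np.log10(pi) + rng.normal(0, 0.1, 30))
        out = stats.region_pi_model(percent, ["NAO"] * 30, pi)
        fit = stats.loglog_fit(percent, pi)
        assert list(out.index) == ["log10_pi"]
        assert out.loc["log10_pi", "p"] == pytest.approx(fit.p_slope, rel=1e-9)
        assert out.loc["log10_pi", "F"] == pytest.approx(
            (fit.slope / fit.se_slope) ** 2, rel=1e-9
        )

    def test_null_region_effect_is_calibrated(self):
        rng = np.random.default_rng(12)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            region = rng.choice(["MS", "NAO", "SPO", "IO"], 60)
            pi = 10 ** rng.uniform(-2, 0, 60)
            percent = 10 ** (-0.5 - 0.8 * np.log10(pi) + rng.normal(0, 0.2, 60))
            out = stats.region_pi_model(percent, region, pi)
            if out.loc["region", "p"] < 0.05:
                rejections += 1
        rate = rejections / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < 3 * se

    def test_power_to_detect_both_predictors(self):
        rng = np.random.default_rng(13)
        offsets = {"MS": 0.4, "NAO": 0.2, "SPO": 0.0, "IO": -0.2}
        detected = 0
        n_reps = 30
        for _ in range(n_reps):
            region = rng.choice(list(offsets), 120)
            pi = 10 ** rng.uniform(-2, 0, 120)
            shift = np.array([offsets[r] for r in region])
            percent = 10 ** (
                -0.5 - 0.8 * np.log10(pi) + shift + rng.normal(0, 0.2, 120)
            )
            out = stats.region_pi_model(percent, region, pi)
            if (out["p"] < 0.05).all():
                detected += 1
        assert detected >= 24  # power > 0.9, 3 sigma binomial slack

    def test_tiny_region_warns_but_is_retained(self):
        rng = np.random.default_rng(14)
        region = ["MS"] * 10 + ["NAO"]
        pi = 10 ** rng.uniform(-2, 0, 11)
        percent = 10 ** (-0.5 - np.log10(pi) + rng.normal(0, 0.1, 11))
        with pytest.warns(UserWarning, match="< 2 samples"):
            out = stats.region_pi_model(percent, region, pi)
        assert "region" in out.index


class TestKruskalWallis:
    def test_hand_rank_formula_two_pairs(self):
        # groups {1,2} and {3,4}: ranks (1,2) vs (3,4), no ties
        H, df, p = stats.kruskal_wallis([1, 2, 3, 4], ["a", "a", "b", "b"])
        n = 4
        expected = 12 / (n * (n + 1)) * (2 * (1.5 - 2.5) ** 2 + 2 * (3.5 - 2.5) ** 2)
        assert H == pytest.approx(expected, rel=1e-12)
        assert df == 1

    def test_two_groups_h_equals_squared_rank_sum_deviate(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 15)  # continuous: no ties
        H, df, _ = stats.kruskal_wallis(
            np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15
        )
        U = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        m, n = len(a), len(b)
        z = (U.statistic - m * n / 2) / np.sqrt(m * n * (m + n + 1) / 12)
        assert H == pytest.approx(z**2, rel=1e-9)

    def test_identical_values_give_h_zero(self):
        H, df, p = stats.kruskal_wallis([2, 2, 2, 2], ["a", "a", "b", "b"])
        assert H == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(stats.DegenerateInputError):
            stats.kruskal_wallis([1, 2], ["a", "a"])


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        adj = stats.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(2, 30)))
        adj = stats.benjamini_hochberg(p)
        # independent oracle: literal step-up definition
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            expected[idx] = running
        assert np.allclose(adj, expected)
        assert (adj >= p - 1e-15).all()
        # monotone in raw-p rank
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPairwiseWilcoxon:
    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(16)
        values = rng.normal(0, 1, 60)
        labels = rng.choice(["MS", "NAO", "SPO", "IO"], 60)
        comp = stats.pairwise_wilcoxon_bh(values, labels)
        raw = comp.pairwise_raw.to_numpy()
        adj = comp.pairwise.to_numpy()
        ok = ~np.isnan(raw)
        assert (adj[ok] >= raw[ok] - 1e-15).all()
        assert np.allclose(adj, adj.T, equal_nan=True)
        assert comp.df == 3

    def test_shifted_region_is_the_only_flagged_one(self):
        rng = np.random.default_rng(17)
        hits, false_flags = 0, 0
        n_reps = 20
        for _ in range(n_reps):
            values, labels = [], []
            for region in ["MS", "NAO", "SPO", "IO"]:
                x = rng.lognormal(0, 0.5, 15)
                if region == "MS":
                    x = x * 10
                values.extend(x)
                labels.extend([region] * 15)
            comp = stats.pairwise_wilcoxon_bh(np.array(values), np.array(labels))
            flagged = set(comp.enriched_flags[comp.enriched_flags].index)
            if flagged == {"MS"}:
                hits += 1
            elif flagged - {"MS"}:
                false_flags += 1
        assert hits >= 17
        assert false_flags == 0

    def test_exchangeable_groups_rarely_flagged(self):
        rng = np.random.default_rng(18)
        any_flag = 0
        for _ in range(30):
            values = rng.normal(0, 1, 45)
            labels = np.repeat(["MS", "NAO", "SPO"], 15)
            comp = stats.pairwise_wilcoxon_bh(values, labels)
            if comp.enriched_flags.any():
                any_flag += 1
        assert any_flag <= 3
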
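"""Inferential layer: exact intervals, paired tests, bootstrap machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from apistrack.stats import (
    clopper_pearson,
    cluster_bootstrap_means,
    concordance,
    mcnemar_test,
    spearman_bootstrap,
    summarize_cohort,
    two_proportion_test,
)


def _cp_bisect(k, n, level=0.95):
    """Oracle: invert the binomial tails by bisection."""
    alpha = (1 - level) / 2

    def solve(f, lo, hi):
        # f is increasing in p with f(lo) < 0 < f(hi)
        for _ in range(60):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        return (lo + hi) / 2

    low = 0.0 if k == 0 else solve(lambda p: sps.binom.sf(k - 1, n, p) - alpha, 0, 1)
    high = 1.0 if k == n else solve(lambda p: alpha - sps.binom.cdf(k, n, p), 0, 1)
    return low, high


class TestClopperPearson:
    def test_boundary_conventions(self):
        assert clopper_pearson(0, 10).ci_low == 0.0
        assert clopper_pearson(10, 10).ci_high == 1.0

    def test_published_escape_rate_reproduced(self):
        # 94 escapes of 174 bees on the first CS+ is the printed 54.0%
        rs = clopper_pearson(94, 174)
        assert rs.rate == pytest.approx(0.540, abs=5e-4)
        assert rs.ci_low < 0.54 < rs.ci_high

    @pytest.mark.parametrize("k,n", [(5, 10), (1, 20), (94, 174), (0, 7), (7, 7)])
    def test_bounds_match_bisection_oracle(self, k, n):
        rs = clopper_pearson(k, n)
        lo, hi = _cp_bisect(k, n)
        assert rs.ci_low == pytest.approx(lo, abs=1e-6)
        assert rs.ci_high == pytest.approx(hi, abs=1e-6)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("n", [20, 174])
    def test_exact_coverage_at_least_nominal(self, p, n):
        """Coverage computed exactly by summing the binomial pmf over the k
        whose interval contains p — always >= 95% for an exact interval."""
        cover = sum(
            sps.binom.pmf(k, n, p)
            for k in range(n + 1)
            if clopper_pearson(k, n).ci_low <= p <= clopper_pearson(k, n).ci_high
        )
        assert cover >= 0.95

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestTwoProportion:
    def test_identical_rates_give_null_result(self):
        stat, df, p = two_proportion_test(10, 40, 10, 40)
        assert stat == 0.0 and p == 1.0 and df == 1

    def test_csplus_vs_csminus_rates_differ(self):
        # 94/174 vs 31/174: the first-trial CS+ vs CS- contrast; the
        # uncorrected chi-square reproduces the published 49.6
        stat, df, p = two_proportion_test(94, 174, 31, 174)
        assert p < 0.001
        stat_u, _, p_u = two_proportion_test(94, 174, 31, 174, correction=False)
        assert stat_u == pytest.approx(49.6, abs=0.1)
        assert p_u < 0.001

    def test_symmetric_under_group_swap(self):
        a = two_proportion_test(12, 50, 4, 45)
        b = two_proportion_test(4, 45, 12, 50)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("k1,n1,k2,n2", [(3, 12, 8, 12), (2, 10, 6, 9), (5, 15, 10, 14)])
    def test_close_to_exact_conditional_oracle(self, k1, n1, k2, n2):
        # continuity-corrected chi-square approximates the exhaustive
        # conditional (Fisher) p on small tables
        _, _, p = two_proportion_test(k1, n1, k2, n2)
        exact = sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]]).pvalue
        assert abs(p - exact) < 0.05

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            two_proportion_test(0, 10, 0, 12)


class TestMcNemar:
    def test_symmetric_discordance_is_null(self):
        stat, _, p = mcnemar_test(5, 5)
        assert stat == 0.0 and p == 1.0

    def test_textbook_statistic(self):
        stat, df, _ = mcnemar_test(15, 5)
        assert stat == pytest.approx(5.0)  # (15-5)^2 / 20
        assert df == 1

    def test_symmetric_under_arm_swap(self):
        assert mcnemar_test(12, 4) == pytest.approx(mcnemar_test(4, 12))

    @pytest.mark.parametrize("b,c", [(15, 5), (10, 0), (6, 4), (20, 10), (3, 0)])
    def test_corrected_variant_tracks_exact_sign_test(self, b, c):
        _, _, p = mcnemar_test(b, c, correction=True)
        exact = min(1.0, 2 * sps.binom.cdf(min(b, c), b + c, 0.5))
        assert abs(p - exact) < 0.02

    def test_no_discordance_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_test(0, 0)


class TestSpearmanBootstrap:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        rho, se = spearman_bootstrap(x, 2 * x + 1, n_boot=50, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_bootstrap(x, -x, n_boot=50, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_formula(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [2.0, 1.0, 3.0, 3.0, 5.0, 4.0]
        rho, _ = spearman_bootstrap(x, y, n_boot=10, seed=0)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(brute, abs=1e-12)

    def test_constant_vector_reported_undefined(self):
        rho, se = spearman_bootstrap([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], n_boot=10, seed=0)
        assert np.isnan(rho) and np.isnan(se)

    def test_reproducible_under_seed(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        assert spearman_bootstrap(x, y, 200, seed=4) == spearman_bootstrap(x, y, 200, seed=4)

    def test_se_shrinks_with_sample_size(self, rng):
        x1 = rng.normal(size=20)
        y1 = x1 + rng.normal(size=20)
        x2 = np.tile(x1, 10)
        y2 = np.tile(y1, 10)
        _, se_small = spearman_bootstrap(x1, y1, 400, seed=0)
        _, se_big = spearman_bootstrap(x2, y2, 400, seed=0)
        assert se_big < se_small


def _cluster_frame(rng, n_clusters=40, shift=0.0):
    rows = []
    for g, delta in (("a", 0.0), ("b", shift)):
        for c in range(n_clusters):
            mu = rng.normal(delta, 1.0)
            for v in rng.normal(mu, 0.5, size=4):
                rows.append({"value": v, "group": g, "bee": f"{g}{c}"})
    return pd.DataFrame(rows)


class TestClusterBootstrap:
    def test_identical_values_give_degenerate_intervals(self):
        frame = pd.DataFrame(
            {"value": [2.0] * 12, "group": ["a"] * 6 + ["b"] * 6,
             "bee": list("xxyyzz") + list("uuvvww")}
        )
        gc = cluster_bootstrap_means(frame, "value", "group", "bee", n_boot=100, seed=0)
        for g in ("a", "b"):
            assert gc.groups[g]["ci_low"] == gc.groups[g]["ci_high"] == 2.0
        assert all(v == 1.0 for v in gc.p_overlap.values())

    def test_interval_contains_group_mean(self, rng):
        frame = _cluster_frame(rng, shift=1.0)
        gc = cluster_bootstrap_means(frame, "value", "group", "bee", n_boot=400, seed=1)
        for g, s in gc.groups.items():
            assert s["ci_low"] <= s["mean"] <= s["ci_high"]

    def test_separated_groups_have_small_overlap(self, rng):
        frame = _cluster_frame(rng, shift=3.0)
        gc = cluster_bootstrap_means(frame, "value", "group", "bee", n_boot=400, seed=1)
        assert gc.p_overlap["a|b"] < 0.05 and gc.p_overlap["b|a"] < 0.05

    def test_null_calibration(self, rng):
        """Exchangeable groups: the overlap probability exceeds 0.05 in at
        least 90% of replicate cohorts."""
        hits = 0
        reps = 20
        for i in range(reps):
            frame = _cluster_frame(rng, n_clusters=25, shift=0.0)
            gc = cluster_bootstrap_means(frame, "value", "group", "bee",
                                         n_boot=200, seed=i)
            if gc.p_overlap["a|b"] > 0.05:
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_interval_coverage_near_nominal(self, rng):
        """95% intervals for a group mean cover the true mean at roughly the
        nominal rate over replicate cohorts (cluster-level CLT regime)."""
        cover = 0
        reps = 100
        for i in range(reps):
            frame = _cluster_frame(rng, n_clusters=30, shift=0.0)
            gc = cluster_bootstrap_means(frame, "value", "group", "bee",
                                         n_boot=200, seed=i)
            s = gc.groups["a"]
            if s["ci_low"] <= 0.0 <= s["ci_high"]:
                cover += 1
        assert cover >= 85  # ~95% nominal with Monte Carlo slack

    def test_reduces_to_plain_bootstrap_with_singleton_clusters(self, rng):
        vals = rng.normal(size=60)
        frame = pd.DataFrame(
            {"value": np.concatenate([vals, vals + 0.1]),
             "group": ["a"] * 60 + ["b"] * 60,
             "bee": [f"a{i}" for i in range(60)] + [f"b{i}" for i in range(60)]}
        )
        gc = cluster_bootstrap_means(frame, "value", "group", "bee", n_boot=600, seed=3)
        # singleton clusters == case resampling: interval close to the
        # classical normal-theory interval for the mean
        se = vals.std(ddof=1) / np.sqrt(60)
        s = gc.groups["a"]
        assert s["ci_low"] == pytest.approx(vals.mean() - 1.96 * se, abs=3 * se / 4)
        assert s["ci_high"] == pytest.approx(vals.mean() + 1.96 * se, abs=3 * se / 4)

    def test_single_cluster_group_rejected(self):
        frame = pd.DataFrame(
            {"value": [1.0, 2.0, 3.0, 4.0], "group": ["a", "a", "b", "b"],
             "bee": ["x", "x", "y", "y"]}
        )
        with pytest.raises(ValueError, match="clusters"):
            cluster_bootstrap_means(frame, "value", "group", "bee", n_boot=10, seed=0)


class TestConcordance:
    def test_identical_and_complementary(self):
        a = [True, False, True, False]
        assert concordance(a, a) == 100.0
        assert concordance(a, [not v for v in a]) == 0.0

    def test_independent_coins_near_half(self, rng):
        a = rng.random(10_000) < 0.5
        b = rng.random(10_000) < 0.5
        assert concordance(a, b) == pytest.approx(50.0, abs=2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concordance([True], [True, False])


class TestSummarizeCohort:
    def test_structure_on_simulated_cohort(self, small_cohort):
        from apistrack.scoring import score_cohort

        frame = score_cohort(small_cohort).to_frame()
        out = summarize_cohort(frame, n_boot=100, seed=0)
        assert set(out["escape_rates"]) == {"1.CS+", "2.CS+", "1.CS-", "2.CS-"}
        assert "velocity_vs_escape" in out["correlations"]
        assert "velocity_cm_s_by_class_all_responses" in out["group_comparisons"]
        for cls, rs in out["escape_rates"].items():
            assert rs["n"] == len(small_cohort)

    def test_degenerate_single_bee_marked(self, small_cohort):
        from apistrack.scoring import score_cohort

        frame = score_cohort(small_cohort[:1]).to_frame()
        out = summarize_cohort(frame, n_boot=50, seed=0)
        assert any(
            "degenerate" in v for v in out["group_comparisons"].values()
        )
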
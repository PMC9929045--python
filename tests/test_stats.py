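import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from relsev import (
    bootstrap_median,
    choose_branch,
    dunn_posthoc,
    friedman_test,
    holm_adjust,
    kruskal_wallis,
    pairwise_wmw,
    parametric_branch,
    shapiro_wilk,
    significance_stars,
)
from relsev.errors import SampleSizeError
from relsev.stats import pairwise_t


# ---------------------------------------------------------------------------
# Independent oracles


def exact_bootstrap_median_distribution(x):
    """Enumerate all n^n equally likely resamples; exact bootstrap law of the
    median (feasible for n <= 6)."""
    x = np.asarray(x, float)
    n = x.size
    meds = [np.median(x[list(idx)]) for idx in itertools.product(range(n), repeat=n)]
    return np.sort(meds)


def hand_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from first principles (mid-ranks)."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / correction


def exact_wmw_p(x, y):
    """Exact two-sided Wilcoxon-Mann-Whitney p by enumerating all C(n+m, n)
    assignments of the pooled (untied) sample."""
    pooled = np.asarray(list(x) + list(y), float)
    n = len(x)
    u_obs = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact").statistic
    m = len(pooled) - n
    u_vals = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)
        u_vals.append(u)
    u_vals = np.asarray(u_vals)
    mid = n * m / 2.0
    return float(np.mean(np.abs(u_vals - mid) >= abs(u_obs - mid) - 1e-12))


def hand_holm(p):
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------


class TestBootstrapMedian:
    def test_constant_sample_degenerates(self):
        est = bootstrap_median([5, 5, 5, 5], B=200, seed=0)
        assert (est.median_hat, est.ci_low, est.ci_high) == (5.0, 5.0, 5.0)

    def test_outlier_sample_ci(self):
        est = bootstrap_median([1, 2, 3, 4, 100], B=10_000, seed=1)
        assert est.ci_low <= 3 <= est.ci_high
        assert 1 <= est.ci_low and est.ci_high <= 100

    def test_matches_exact_enumeration(self):
        """Percentile CI approximates the exact bootstrap quantiles of the
        5^5-resample distribution."""
        x = [1, 2, 3, 4, 100]
        exact = exact_bootstrap_median_distribution(x)
        lo, hi = np.quantile(exact, [0.025, 0.975])
        est = bootstrap_median(x, B=20_000, seed=2)
        assert est.ci_low == pytest.approx(lo, abs=1.0)
        assert est.ci_high == pytest.approx(hi, abs=5.0)  # atom at 100 makes the tail lumpy
        assert est.median_hat == pytest.approx(np.median(exact), abs=0.5)

    def test_seed_reproducibility_is_bit_identical(self):
        a = bootstrap_median([3.1, 1.4, 1.5, 9.2, 6.5], B=5000, seed=99)
        b = bootstrap_median([3.1, 1.4, 1.5, 9.2, 6.5], B=5000, seed=99)
        assert a == b

    def test_small_sample_errors(self):
        with pytest.raises(SampleSizeError):
            bootstrap_median([1.0], B=100, seed=0)

    def test_bca_is_available(self):
        est = bootstrap_median([1, 2, 3, 4, 5, 6, 7, 8], B=2000, seed=3, method="bca")
        assert est.ci_low <= est.median_hat <= est.ci_high


class TestShapiroAndBranch:
    def test_bimodal_sample_rejected(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-4, 0.5, 25), rng.normal(4, 0.5, 25)])
        assert shapiro_wilk(x).p_raw <= 0.05

    def test_null_p_values_are_uniform(self):
        """Type-I calibration: over replicates of normal data the p-value is
        Uniform(0,1) (Kolmogorov-Smirnov check in aggregate)."""
        rng = np.random.default_rng(6)
        ps = [shapiro_wilk(rng.normal(size=50)).p_raw for _ in range(300)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_sample_flags_nonparametric(self):
        r = shapiro_wilk([2.0, 2.0, 2.0, 2.0])
        assert math.isnan(r.p_raw) and "constant" in r.note
        branch, _ = choose_branch({"a": [2.0, 2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0, 2.5]})
        assert branch == "nonparametric"

    def test_normal_groups_go_parametric(self):
        rng = np.random.default_rng(7)
        groups = {k: rng.normal(size=40) for k in "abc"}
        assert choose_branch(groups)[0] == "parametric"

    def test_skewed_group_goes_nonparametric(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(size=40), "b": rng.lognormal(0, 1.5, size=40)}
        assert choose_branch(groups)[0] == "nonparametric"


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        r = kruskal_wallis({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        r = kruskal_wallis({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert r.statistic == pytest.approx(3.857, abs=1e-3)
        assert r.df == 1

    def test_matches_hand_ranks_on_small_instances(self):
        """Statistic equals a from-scratch mid-rank computation on every
        random instance with total n <= 8, ties included."""
        rng = np.random.default_rng(11)
        for sizes in [(2, 2), (3, 3), (4, 4), (2, 3, 3), (2, 2, 2, 2), (3, 5)]:
            for _ in range(30):
                groups = [list(rng.integers(0, 6, size=s).astype(float)) for s in sizes]
                if np.ptp(np.concatenate(groups)) == 0:
                    continue
                r = kruskal_wallis({str(i): g for i, g in enumerate(groups)})
                assert r.statistic == pytest.approx(hand_kruskal_h(groups), rel=1e-10)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(12)
        rej = sum(
            kruskal_wallis({k: rng.normal(size=10) for k in "abc"}).p_raw <= 0.05
            for _ in range(1000)
        )
        assert 0.03 <= rej / 1000 <= 0.075

    def test_arity_error(self):
        with pytest.raises(SampleSizeError):
            kruskal_wallis({"a": [1, 2, 3]})


class TestPairwiseWMW:
    def test_identical_pair_not_significant(self):
        [r] = pairwise_wmw({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert r.p_raw > 0.5

    def test_fully_separated_triples_exact_p(self):
        [r] = pairwise_wmw({"a": [1, 2, 3], "b": [10, 20, 30]})
        assert r.p_raw == pytest.approx(0.1, abs=1e-12)  # smallest attainable for 3 vs 3

    def test_matches_enumeration_on_small_untied_instances(self):
        rng = np.random.default_rng(13)
        for nx, ny in [(2, 3), (3, 3), (3, 4), (4, 4), (2, 6)]:
            for _ in range(10):
                pooled = rng.choice(1000, size=nx + ny, replace=False).astype(float)
                x, y = list(pooled[:nx]), list(pooled[nx:])
                [r] = pairwise_wmw({"x": x, "y": y})
                assert r.p_raw == pytest.approx(exact_wmw_p(x, y), abs=1e-12)

    def test_three_groups_form_a_holm_family_of_three(self):
        res = pairwise_wmw({"a": [1, 2], "b": [3, 4], "c": [5, 6]})
        assert len(res) == 3
        np.testing.assert_allclose(
            [r.p_adj for r in res], hand_holm([r.p_raw for r in res]), rtol=1e-12
        )


class TestHolm:
    def test_hand_step_down_triple(self):
        assert holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.3]) == [0.3]

    def test_cap_and_monotonicity(self):
        assert holm_adjust([0.5, 0.6]) == pytest.approx([1.0, 1.0])

    def test_permutation_invariant_and_dominating(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(size=7)
        adj = np.asarray(holm_adjust(p))
        assert np.all(adj >= p)
        perm = rng.permutation(7)
        adj_perm = np.asarray(holm_adjust(p[perm]))
        np.testing.assert_allclose(adj_perm, adj[perm], rtol=1e-12)
        np.testing.assert_allclose(adj, hand_holm(p), rtol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.2])


class TestFriedman:
    def test_constant_rows_give_zero(self):
        m = np.tile([3.0, 3.0, 3.0], (4, 1))
        r = friedman_test(m)
        assert r.statistic == 0.0 and r.df == 2

    def test_unanimous_ranking(self):
        m = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], float)
        r = friedman_test(m)
        assert r.statistic == pytest.approx(6.0)
        assert r.df == 2

    def test_column_shuffle_regenerates_the_null(self):
        """Permuting each subject's conditions independently makes the data
        exchangeable across conditions; the test then rejects at its nominal
        rate (permutation-oracle calibration)."""
        rng = np.random.default_rng(15)
        m = rng.normal(size=(10, 4)) + np.array([0.0, 1.0, 2.0, 3.0])  # real effect
        rej = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = np.array([rng.permutation(row) for row in m])
            rej += friedman_test(perm).p_raw <= 0.05
        assert 0.01 <= rej / n_perm <= 0.10
        # the un-shuffled matrix, by contrast, carries a strong day effect
        assert friedman_test(m).p_raw <= 0.001

    def test_incomplete_block_errors(self):
        m = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(SampleSizeError):
            friedman_test(m)


class TestDunn:
    def test_identical_groups_near_one(self):
        g = {"ctrl": [1, 2, 3, 4], "a": [1, 2, 3, 4], "b": [1, 2, 3, 4]}
        for r in dunn_posthoc(g, control="ctrl"):
            assert r.p_adj == pytest.approx(1.0)

    def test_k_groups_give_k_minus_one_comparisons(self):
        g = {"ctrl": [1.0, 2.0], "a": [2.0, 3.0], "b": [3.0, 4.0], "c": [4.0, 5.0]}
        assert len(dunn_posthoc(g, control="ctrl")) == 3

    def test_two_group_decision_agrees_with_wmw(self):
        """Cross-method consistency: on clearly separated or clearly equal
        seeded data, Dunn-vs-control and WMW reach the same verdict."""
        rng = np.random.default_rng(16)
        for shift in (0.0, 3.0):
            a = rng.normal(size=12)
            b = rng.normal(loc=shift, size=12)
            dunn = dunn_posthoc({"ctrl": a, "t": b}, control="ctrl")[0]
            wmw = pairwise_wmw({"ctrl": a, "t": b})[0]
            assert (dunn.p_adj <= 0.05) == (wmw.p_adj <= 0.05)

    def test_unknown_control_errors(self):
        with pytest.raises(KeyError):
            dunn_posthoc({"a": [1.0, 2.0], "b": [2.0, 3.0]}, control="zz")


class TestParametricBranch:
    def test_between_type_one_error(self):
        rng = np.random.default_rng(17)
        rej = 0
        for _ in range(500):
            groups = {"a": rng.normal(size=12), "b": rng.normal(size=12)}
            if parametric_branch(groups, design="between")[0].p_raw <= 0.05:
                rej += 1
        assert 0.025 <= rej / 500 <= 0.08

    def test_within_identical_columns_f_zero(self):
        import pandas as pd

        df = pd.DataFrame({"d0": [1.0, 2.0, 3.0], "d1": [1.0, 2.0, 3.0]})
        r = parametric_branch(df, design="within")[0]
        assert r.statistic == 0.0

    def test_dunnett_gives_k_minus_one_comparisons(self):
        rng = np.random.default_rng(18)
        groups = {k: rng.normal(size=8) for k in ("ctrl", "a", "b", "c")}
        res = parametric_branch(groups, design="between", control="ctrl")
        assert [r.test_name for r in res] == ["anova_oneway", "dunnett", "dunnett", "dunnett"]

    def test_within_with_effect_and_control_column(self):
        import pandas as pd

        rng = np.random.default_rng(19)
        base = rng.normal(size=10)
        df = pd.DataFrame({"d-1": base, "d0": base - 3 + rng.normal(0, 0.3, 10),
                           "d1": base - 1 + rng.normal(0, 0.3, 10)})
        res = parametric_branch(df, design="within", control="d-1")
        assert res[0].test_name == "rm_anova" and res[0].p_raw <= 0.05
        assert len(res) == 3

    def test_pairwise_t_family(self):
        rng = np.random.default_rng(20)
        res = pairwise_t({k: rng.normal(size=10) for k in "abc"})
        assert len(res) == 3 and all(r.p_adj >= r.p_raw for r in res)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00005, "****"), (0.2, "ns")],
    )
    def test_thresholds(self, p, label):
        assert significance_stars(p) == label
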
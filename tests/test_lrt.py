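import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from dirichlet_lrt import (
    FilterSpec,
    FitError,
    chi2_pvalue,
    dirichlet_lrt,
    lrt_statistic,
    randomization_pvalue,
    recommend_method,
)
from dirichlet_lrt.lrt import LRTResult

from conftest import dirichlet_table, make_table


def direct_optimizer_D(table):
    """Independent oracle: maximize the Dirichlet log-likelihood directly
    with a generic quasi-Newton optimizer over log-parameters."""

    def neg_ll(log_alpha, groups):
        alpha = np.exp(log_alpha)
        total = 0.0
        for g in groups:
            n = g.shape[0]
            total += n * (gammaln(alpha.sum()) - gammaln(alpha).sum())
            total += ((alpha - 1.0) * np.log(g).sum(axis=0)).sum()
        return -total

    def maximize(groups, k):
        best = None
        for start in (np.zeros(k), np.log(np.full(k, 5.0)), np.log(np.full(k, 0.5))):
            r = minimize(neg_ll, start, args=(groups,), method="L-BFGS-B",
                         options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-12})
            if best is None or r.fun < best:
                best = r.fun
        return -best

    k = table.n_classes
    logL0 = maximize([table.values], k)
    logL1 = sum(
        maximize([table.group_values(env)], k) for env in table.env_labels
    )
    return 2.0 * (logL1 - logL0), logL0, logL1


class TestStatistic:
    def test_identical_groups_give_zero(self, rng):
        x = rng.dirichlet([2, 5, 3], size=6)
        values = np.vstack([x, x])
        t = make_table(values, ["a"] * 6 + ["b"] * 6, is_normalized=True)
        D, logL0, logL1, *_ = lrt_statistic(t)
        assert D == pytest.approx(0.0, abs=1e-6)
        assert logL1 >= logL0 - 1e-9

    def test_matches_direct_optimizer(self, two_env_table):
        D, logL0, logL1, *_ = lrt_statistic(two_env_table)
        D_ref, logL0_ref, logL1_ref = direct_optimizer_D(two_env_table)
        assert logL0 == pytest.approx(logL0_ref, abs=1e-5)
        assert logL1 == pytest.approx(logL1_ref, abs=1e-5)
        assert D == pytest.approx(D_ref, abs=1e-4)

    def test_class_permutation_invariance(self, two_env_table):
        D, *_ = lrt_statistic(two_env_table)
        perm = [2, 0, 1]
        t = make_table(
            two_env_table.values[:, perm],
            two_env_table.environments,
            class_names=tuple(two_env_table.class_names[p] for p in perm),
            is_normalized=True,
        )
        D_perm, *_ = lrt_statistic(t)
        assert D_perm == pytest.approx(D, rel=1e-9)

    def test_sample_order_invariance(self, two_env_table):
        order = list(range(20))
        order[0:10] = order[9::-1]  # reverse within env1
        t = make_table(
            two_env_table.values[order],
            [two_env_table.environments[i] for i in order],
            is_normalized=True,
        )
        D, *_ = lrt_statistic(two_env_table)
        D2, *_ = lrt_statistic(t)
        assert D2 == pytest.approx(D, rel=1e-9)

    def test_env_relabel_invariance(self, two_env_table):
        relabeled = ["X" if e == "env1" else "Y" for e in two_env_table.environments]
        D, *_ = lrt_statistic(two_env_table)
        D2, *_ = lrt_statistic(two_env_table.with_environments(relabeled))
        assert D2 == pytest.approx(D, rel=1e-12)

    def test_singleton_group_rejected(self, rng):
        t = make_table(
            rng.dirichlet([2, 5, 3], size=4),
            ["a", "a", "a", "b"],
            is_normalized=True,
        )
        with pytest.raises(ValueError, match="singleton"):
            lrt_statistic(t)

    def test_one_environment_rejected(self, rng):
        t = make_table(rng.dirichlet([2, 5, 3], size=4), ["a"] * 4,
                       is_normalized=True)
        with pytest.raises(ValueError, match="2 environments"):
            lrt_statistic(t)

    def test_zero_entries_rejected(self):
        t = make_table(
            [[0.5, 0.5, 0.0], [0.2, 0.3, 0.5]] * 2,
            ["a", "a", "b", "b"],
            is_normalized=True,
        )
        with pytest.raises(ValueError, match="zero"):
            lrt_statistic(t)


class TestChi2Pvalue:
    def test_zero_statistic_full_tail(self):
        assert chi2_pvalue(0.0, 3, 5) == 1.0

    def test_df_is_m_minus_1_times_k(self):
        # m=8 environments, K=8 classes -> 56 additional parameters
        from scipy.stats import chi2 as chi2_dist

        assert chi2_pvalue(10.0, 8, 8) == pytest.approx(chi2_dist.sf(10.0, 56))

    def test_reference_table_value(self):
        # published chi-squared table: upper 5% point for 10 df is 18.307
        assert chi2_pvalue(18.307, 3, 5) == pytest.approx(0.05, abs=5e-5)

    def test_tiny_tail_representable(self):
        p = chi2_pvalue(1500.0, 2, 21)
        assert 0 < p < 1e-280

    @pytest.mark.parametrize("m,k", [(1, 5), (2, 1), (0, 0)])
    def test_invalid_df(self, m, k):
        with pytest.raises(ValueError):
            chi2_pvalue(1.0, m, k)

    def test_negative_statistic(self):
        with pytest.raises(ValueError):
            chi2_pvalue(-1.0, 2, 5)


class TestRecommendMethod:
    def test_large_n_prefers_chi2(self):
        assert recommend_method(354, 2, 21) == "chi2"

    def test_small_n_prefers_randomization(self):
        assert recommend_method(12, 3, 9) == "randomization"

    def test_boundary_inclusive(self):
        assert recommend_method(2 * 3 * 5, 3, 5) == "chi2"
        assert recommend_method(2 * 3 * 5 - 1, 3, 5) == "randomization"

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            recommend_method(0, 2, 3)


def enumerate_assignments_pvalue(table):
    """Brute force: distinct equal-split label assignments for 2 envs x 2
    samples, statistic recomputed for each; exceedance proportion."""
    D_obs, *_ = lrt_statistic(table)
    ids = range(table.n_samples)
    stats = []
    for combo in itertools.combinations(ids, 2):
        labels = ["b"] * table.n_samples
        for i in combo:
            labels[i] = "a"
        D, *_ = lrt_statistic(table.with_environments(labels))
        stats.append(D)
    return sum(d >= D_obs - 1e-12 for d in stats) / len(stats), stats


class TestRandomization:
    def test_converges_to_enumeration(self):
        t = dirichlet_table([(2, 5, 3), (6, 2, 2)], [2, 2], seed=3)
        p_exact, _ = enumerate_assignments_pvalue(t)
        rng = np.random.default_rng(0)
        p_rand, n_exceed = randomization_pvalue(t, 3000, rng)
        se = np.sqrt(p_exact * (1 - p_exact) / 3000) + 1e-12
        assert abs(p_rand - p_exact) <= max(4 * se, 0.01)
        assert n_exceed == round(p_rand * 3000)

    def test_full_label_permutations_match_distinct_assignments(self):
        # all 4! label-vector permutations induce exactly the 6 distinct
        # splits, so both enumerations give identical statistic multisets
        t = dirichlet_table([(2, 5, 3), (6, 2, 2)], [2, 2], seed=3)
        _, distinct = enumerate_assignments_pvalue(t)
        labels = list(t.environments)
        perm_stats = []
        for perm in itertools.permutations(range(4)):
            D, *_ = lrt_statistic(
                t.with_environments([labels[i] for i in perm])
            )
            perm_stats.append(D)
        assert np.allclose(
            np.sort(np.repeat(np.sort(distinct), 4)), np.sort(perm_stats),
            rtol=1e-9,
        )

    def test_zero_exceedance_reported_as_bound(self):
        res = LRTResult(
            D=50.0, df=6, logL0=-10.0, logL1=15.0,
            alpha_null=None, alpha_alt={}, method_used="randomization",
            p_rand=0.0, n_rand_trials=5000, n_exceed=0,
        )
        assert res.p_rand_display == "p < 0.0002"

    def test_invalid_trials(self, null_table):
        with pytest.raises(ValueError):
            randomization_pvalue(null_table, 0)

    def test_deterministic_under_seed(self, null_table):
        p1, _ = randomization_pvalue(null_table, 50, np.random.default_rng(9))
        p2, _ = randomization_pvalue(null_table, 50, np.random.default_rng(9))
        assert p1 == p2


class TestPipeline:
    def test_method_both(self, two_env_table):
        res = dirichlet_lrt(two_env_table, method="both", n_trials=50, seed=1)
        assert res.method_used == "both"
        assert res.p_chi2 is not None and res.p_rand is not None
        assert res.df == (res.m - 1) * res.K
        assert res.D == pytest.approx(-2 * (res.logL0 - res.logL1), abs=1e-9)
        assert res.logL1 >= res.logL0 - 1e-9
        assert res.n_rand_trials == 50
        assert res.p_rand == res.n_exceed / 50

    def test_auto_large_n_uses_chi2_only(self):
        t = dirichlet_table([(2, 5, 3), (5, 2, 3)], [30, 30], seed=5)
        res = dirichlet_lrt(t, method="auto")
        assert res.method_used == "chi2"
        assert res.p_chi2 is not None
        assert res.p_rand is None

    def test_auto_small_n_uses_randomization(self, null_table):
        res = dirichlet_lrt(null_table, method="auto", n_trials=30, seed=2)
        assert res.method_used == "randomization"
        assert res.p_rand is not None and res.p_chi2 is None

    def test_filter_report_attached(self):
        t = dirichlet_table([(20, 50, 30, 0.01), (50, 20, 30, 0.01)],
                            [5, 5], seed=8)
        res = dirichlet_lrt(t, FilterSpec(min_proportion=0.01), method="chi2")
        assert res.filter_report is not None
        assert res.filter_report.K_before == 4
        assert res.K == res.filter_report.K_after

    def test_counts_accepted(self):
        # raw counts normalize internally to the same result as proportions
        rng = np.random.default_rng(31)
        props = rng.dirichlet([2, 5, 3], size=8)
        counts = props * 10_000
        envs = ["a"] * 4 + ["b"] * 4
        r1 = dirichlet_lrt(make_table(props, envs), method="chi2")
        r2 = dirichlet_lrt(make_table(counts, envs), method="chi2")
        assert r1.D == pytest.approx(r2.D, rel=1e-9)

    def test_unknown_method(self, null_table):
        with pytest.raises(ValueError, match="method"):
            dirichlet_lrt(null_table, method="bogus")

    def test_summary_states_geometry(self, null_table):
        res = dirichlet_lrt(null_table, method="both", n_trials=20, seed=4)
        text = res.summary()
        for token in ("m", "K", "df", "seed", "randomization"):
            assert token in text
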
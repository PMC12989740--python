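"""Adjustment procedures: worked examples, oracles, and dominance laws."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from effectsim import (
    AdjustmentContext,
    adjust,
    adjust_pvalues,
    attainable_true_counts,
    dunnett_single,
    dunnett_stepdown,
    enumerate_pairs,
    max_abs_t_cdf,
    pooled_stats,
    shaffer_s2,
    tukey_single,
    tukey_stepdown,
)
from effectsim.datagen import GroupSample


def _ctx(method, k, mode="all_pairwise", control=None, **kw):
    cs = enumerate_pairs(k, mode, control=control)
    return AdjustmentContext(method=method, k=k, comparison_set=cs, **kw)


class TestPValueMethods:
    def test_bonferroni_triple(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bonferroni"), [0.03, 0.06, 0.09]
        )

    def test_holm_step_down(self):
        # oracle: cumulative max of p_(i) * (m - i + 1)
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "holm"), [0.03, 0.04, 0.04]
        )
        np.testing.assert_allclose(
            adjust_pvalues([0.001, 0.001, 0.001], "holm"), [0.003, 0.003, 0.003]
        )

    def test_hochberg_reversed_holm(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.04, 0.04], "hochberg"), [0.04, 0.04]
        )

    def test_bh_step_up(self):
        # oracle: min over j >= i of p_(j) * m / j
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh"), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize(
        "method", ["bonferroni", "holm", "hochberg", "hommel", "bh"]
    )
    def test_single_hypothesis_identity(self, method):
        np.testing.assert_allclose(adjust_pvalues([0.5], method), [0.5])

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5], "holm")
        with pytest.raises(ValueError):
            adjust_pvalues([1.5], "holm")

    def test_hommel_matches_simes_closed_testing_oracle(self):
        """Brute-force closed testing with Simes local tests."""

        def oracle(p):
            m = len(p)
            adj = np.zeros(m)
            for i in range(m):
                worst = 0.0
                for r in range(1, m + 1):
                    for S in itertools.combinations(range(m), r):
                        if i not in S:
                            continue
                        ps = np.sort(np.asarray(p)[list(S)])
                        simes = np.min(len(S) * ps / np.arange(1, len(S) + 1))
                        worst = max(worst, simes)
                adj[i] = min(worst, 1.0)
            return adj

        rng = np.random.default_rng(8)
        for m in (2, 3, 4):
            for _ in range(20):
                p = rng.uniform(0.001, 0.9, size=m)
                np.testing.assert_allclose(
                    adjust_pvalues(p, "hommel"), oracle(p), atol=1e-10
                )

    def test_dominance_chain_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(1e-4, 1.0, size=m)
            bonf = adjust_pvalues(p, "bonferroni")
            holm_ = adjust_pvalues(p, "holm")
            hoch = adjust_pvalues(p, "hochberg")
            homm = adjust_pvalues(p, "hommel")
            assert np.all(bonf >= holm_ - 1e-12)
            assert np.all(holm_ >= hoch - 1e-12)
            assert np.all(hoch >= homm - 1e-12)
            assert np.all(homm >= p - 1e-12)


class TestDunnett:
    def test_one_comparison_reduces_to_raw(self):
        ctx = _ctx("dunnett", 2, "many_to_one", control=1,
                   per_group_n=(10, 10), pooled_df=18.0)
        adj = dunnett_single([2.0], ctx)
        raw = 2 * sps.t.sf(2.0, 18.0)
        assert adj[0] == pytest.approx(raw, abs=1e-4)

    def test_zero_statistic_gives_one(self):
        ctx = _ctx("dunnett", 3, "many_to_one", control=1,
                   per_group_n=(10, 10, 10), pooled_df=27.0)
        assert dunnett_single([0.0, 1.0], ctx)[0] == pytest.approx(1.0)

    def test_against_monte_carlo_bivariate_t_oracle(self):
        """k=3 equal n: max-|T| tail with rho=0.5 from 1e6 simulated draws."""
        ctx = _ctx("dunnett", 3, "many_to_one", control=1,
                   per_group_n=(10, 10, 10), pooled_df=27.0)
        adj = dunnett_single([2.0, 2.0], ctx)
        rng = np.random.default_rng(2718)
        lam = 1.0 / np.sqrt(2.0)
        z0 = rng.standard_normal(10**6)
        z = rng.standard_normal((10**6, 2))
        x = lam * z0[:, None] + np.sqrt(1 - lam**2) * z
        u = np.sqrt(rng.chisquare(27, 10**6) / 27)
        mc = np.mean(np.max(np.abs(x), axis=1) / u > 2.0)
        assert adj[0] == pytest.approx(mc, abs=2e-3)

    def test_matches_scipy_dunnett(self):
        rng = np.random.default_rng(4)
        groups = [GroupSample(i + 1, rng.normal(0.3 * i, 1, 12)) for i in range(4)]
        cs = enumerate_pairs(4, "many_to_one", control=1)
        t, df = pooled_stats(groups, cs)
        ctx = AdjustmentContext("dunnett", 4, cs, per_group_n=(12,) * 4, pooled_df=df)
        ours = dunnett_single(t, ctx)
        ref = sps.dunnett(
            *[g.values for g in groups[1:]], control=groups[0].values,
            rng=np.random.default_rng(0),
        )
        np.testing.assert_allclose(ours, ref.pvalue, atol=2e-3)

    def test_stepdown_dominates_single_step(self):
        rng = np.random.default_rng(6)
        ctx = _ctx("dunnett_stepdown", 5, "many_to_one", control=1,
                   per_group_n=(8,) * 5, pooled_df=35.0)
        for _ in range(30):
            t = rng.normal(0, 2, size=4)
            sd = dunnett_stepdown(t, ctx)
            ss = dunnett_single(t, ctx)
            assert np.all(sd <= ss + 1e-10)
            order = np.argsort(-np.abs(t))
            assert np.all(np.diff(sd[order]) >= -1e-12)  # monotonized

    def test_stepdown_matches_closed_testing_enumeration(self):
        """All 2^3 - 1 intersections tested with the exact max-|T| tail."""
        ctx = _ctx("dunnett_stepdown", 4, "many_to_one", control=1,
                   per_group_n=(10,) * 4, pooled_df=36.0)
        lam = 1.0 / np.sqrt(2.0)
        rng = np.random.default_rng(14)
        for _ in range(10):
            t = rng.normal(0, 2, size=3)
            expected = np.zeros(3)
            for i in range(3):
                worst = 0.0
                for r in range(1, 4):
                    for S in itertools.combinations(range(3), r):
                        if i not in S:
                            continue
                        stat = np.max(np.abs(t)[list(S)])
                        p_local = 1.0 - max_abs_t_cdf(stat, (lam,) * len(S), 36.0)
                        worst = max(worst, p_local)
                expected[i] = worst
            np.testing.assert_allclose(dunnett_stepdown(t, ctx), expected, atol=1e-3)

    def test_requires_many_to_one(self):
        with pytest.raises(ValueError):
            _ctx("dunnett", 3, "all_pairwise", per_group_n=(5, 5, 5), pooled_df=12.0)


class TestTukey:
    def test_two_groups_reduce_to_raw(self):
        ctx = _ctx("tukey", 2, per_group_n=(9, 9), pooled_df=16.0)
        raw = 2 * sps.t.sf(1.7, 16.0)
        assert tukey_single([1.7], ctx)[0] == pytest.approx(raw, abs=1e-6)
        assert tukey_stepdown([1.7], ctx)[0] == pytest.approx(raw, abs=1e-6)

    def test_zero_statistic_gives_one(self):
        ctx = _ctx("tukey", 3, per_group_n=(8,) * 3, pooled_df=21.0)
        assert tukey_single([0.0, 1.0, 0.5], ctx)[0] == pytest.approx(1.0)

    def test_against_monte_carlo_studentized_range_oracle(self):
        """k=3, df=15: P(range of 3 means > sqrt(2)|t| * s) from 1e6 draws."""
        ctx = _ctx("tukey", 3, per_group_n=(6,) * 3, pooled_df=15.0)
        adj = tukey_single([2.5, 0.3, 0.2], ctx)
        rng = np.random.default_rng(31415)
        z = rng.standard_normal((10**6, 3))
        u = np.sqrt(rng.chisquare(15, 10**6) / 15)
        q = (z.max(axis=1) - z.min(axis=1)) / u
        mc = np.mean(q > np.sqrt(2.0) * 2.5)
        assert adj[0] == pytest.approx(mc, abs=2e-3)

    def test_stepdown_dominates_single_step(self):
        rng = np.random.default_rng(9)
        ctx = _ctx("tukey_stepdown", 4, per_group_n=(7,) * 4, pooled_df=24.0)
        for _ in range(30):
            t = rng.normal(0, 2, size=6)
            sd = tukey_stepdown(t, ctx)
            ss = tukey_single(t, ctx)
            assert np.all(sd <= ss + 1e-10)

    def test_stepdown_matches_closed_testing_enumeration_k3(self):
        """For k=3 any two pairwise equalities imply the global null, so the
        closure has range-3 tests for every |S| >= 2 and range-2 tests for
        singletons."""
        ctx = _ctx("tukey_stepdown", 3, per_group_n=(6,) * 3, pooled_df=15.0)
        rng = np.random.default_rng(27)
        for _ in range(10):
            t = np.abs(rng.normal(0, 2, size=3))
            global_p = float(sps.studentized_range.sf(np.sqrt(2) * t.max(), 3, 15))
            expected = np.array(
                [max(global_p, 2 * sps.t.sf(ti, 15)) for ti in t]
            )
            np.testing.assert_allclose(tukey_stepdown(t, ctx), expected, atol=1e-3)

    def test_requires_all_pairwise(self):
        with pytest.raises(ValueError):
            _ctx("tukey", 3, "many_to_one", control=1,
                 per_group_n=(5,) * 3, pooled_df=12.0)


class TestShafferS2:
    def test_attainable_counts_from_partitions(self):
        assert attainable_true_counts(3) == (3, 1, 0)
        assert attainable_true_counts(4) == (6, 3, 2, 1, 0)
        assert attainable_true_counts(5) == (10, 6, 4, 3, 2, 1, 0)

    def test_k3_multipliers_collapse_after_first_rejection(self):
        """Rejecting one of three pairwise equalities leaves at most one
        hypothesis that can still be true, so later multipliers are 1."""
        ctx = _ctx("s2", 3, pooled_df=15.0)
        np.testing.assert_allclose(
            shaffer_s2([0.01, 0.02, 0.03], ctx), [0.03, 0.03, 0.03]
        )

    def test_single_pair_identity(self):
        ctx = _ctx("s2", 2, pooled_df=10.0)
        np.testing.assert_allclose(shaffer_s2([0.2], ctx), [0.2])

    def test_dominates_holm(self):
        rng = np.random.default_rng(21)
        ctx = _ctx("s2", 4, pooled_df=20.0)
        for _ in range(200):
            p = rng.uniform(1e-4, 1.0, size=6)
            assert np.all(shaffer_s2(p, ctx) <= adjust_pvalues(p, "holm") + 1e-12)


class TestDispatcher:
    def test_none_is_identity(self):
        ctx = _ctx("none", 3)
        p = [0.1, 0.5, 0.9]
        np.testing.assert_allclose(adjust(p, ctx), p)

    def test_tstat_methods_require_statistics(self):
        ctx = _ctx("tukey", 3, per_group_n=(6,) * 3, pooled_df=15.0)
        with pytest.raises(ValueError):
            adjust([0.1, 0.2, 0.3], ctx)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(33)
        for method in ("bonferroni", "holm", "hochberg", "hommel", "bh"):
            p = rng.uniform(1e-3, 1, size=6)
            ctx = _ctx(method, 4)
            assert np.all(adjust(p, ctx) >= p - 1e-12)

    def test_pooled_stats_one_way_layout(self):
        rng = np.random.default_rng(41)
        groups = [GroupSample(i + 1, rng.normal(0, 1, 6)) for i in range(3)]
        t, df = pooled_stats(groups, enumerate_pairs(3))
        assert df == pytest.approx(15.0)
        # cross-check one statistic against the pooled formula
        s2 = np.mean([g.values.var(ddof=1) for g in groups])
        expect = (groups[1].values.mean() - groups[0].values.mean()) / np.sqrt(
            s2 * (2 / 6)
        )
        assert t[0] == pytest.approx(expect)
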
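"""Rank-based testing machinery: BH, Kruskal-Wallis, gated post-hoc
tests, the stratified blocked test, Spearman screens and diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

import pdmeta as m

from conftest import random_count_matrix


def bh_bruteforce(p):
    """Direct reading of the BH step function: q_i = min over j with
    p_(j) >= p_i-rank of m p_(j) / j."""
    p = np.asarray(p, float)
    mm = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(mm)
    for rank_pos in range(mm):
        candidates = [mm * p[order[j]] / (j + 1) for j in range(rank_pos, mm)]
        q[order[rank_pos]] = min(1.0, min(candidates))
    return q


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(m.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_trivial_cases(self):
        assert m.bh_adjust([0.3]) == pytest.approx([0.3])
        np.testing.assert_array_equal(m.bh_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_against_bruteforce_and_statsmodels(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            q = m.bh_adjust(p)
            np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, p):
        p = np.array(p)
        perm = np.random.default_rng(1).permutation(len(p))
        np.testing.assert_allclose(m.bh_adjust(p)[perm], m.bh_adjust(p[perm]), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.bh_adjust([0.5, 1.5])


class TestKruskalWallis:
    def test_hand_computed_example(self):
        df = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["f"], columns=list("abcdef")).astype(float)
        res = m.kruskal_wallis_all(df, ["g1"] * 3 + ["g2"] * 3)
        assert res["statistic"].iloc[0] == pytest.approx(3.857, abs=1e-3)
        assert res["p"].iloc[0] == pytest.approx(0.0495, abs=1e-3)

    def test_label_symmetry(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.random((5, 12)), columns=[f"s{i}" for i in range(12)])
        g = ["a"] * 6 + ["b"] * 6
        swapped = ["b"] * 6 + ["a"] * 6
        np.testing.assert_allclose(
            m.kruskal_wallis_all(df, g)["p"], m.kruskal_wallis_all(df, swapped)["p"])

    def test_constant_feature_degenerate(self):
        df = pd.DataFrame([[2.0] * 8], index=["f"], columns=[f"s{i}" for i in range(8)])
        res = m.kruskal_wallis_all(df, ["a"] * 4 + ["b"] * 4)
        assert res["p"].iloc[0] == 1.0 and bool(res["degenerate"].iloc[0])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 5, size=(10, 15)).astype(float)  # plenty of ties
        df = pd.DataFrame(X, columns=[f"s{i}" for i in range(15)])
        g = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        res = m.kruskal_wallis_all(df, g)
        for i in range(10):
            if res["degenerate"].iloc[i]:
                continue
            ref = stats.kruskal(X[i, g == "a"], X[i, g == "b"], X[i, g == "c"])
            assert res["statistic"].iloc[i] == pytest.approx(ref.statistic, rel=1e-10)
            assert res["p"].iloc[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_two_group_kw_equals_wilcoxon_order(self):
        """On tie-free data the two-group KW chi-square p matches the
        normal-approximation Wilcoxon p."""
        rng = np.random.default_rng(4)
        x = rng.normal(size=16)
        df = pd.DataFrame([x], index=["f"], columns=[f"s{i}" for i in range(16)])
        g = ["a"] * 8 + ["b"] * 8
        p_kw = m.kruskal_wallis_all(df, g)["p"].iloc[0]
        p_w = stats.mannwhitneyu(x[:8], x[8:], alternative="two-sided",
                                 method="asymptotic", use_continuity=False).pvalue
        assert p_kw == pytest.approx(p_w, rel=1e-9)


class TestPosthocPairwise:
    def _setup(self, rng, n_groups=3):
        df = pd.DataFrame(rng.random((6, 6 * n_groups)),
                          columns=[f"s{i}" for i in range(6 * n_groups)])
        g = np.repeat([f"g{i}" for i in range(n_groups)], 6)
        return df, g

    def test_gate_excludes_high_omnibus_p(self):
        rng = np.random.default_rng(5)
        df, g = self._setup(rng)
        omnibus = m.kruskal_wallis_all(df, g)
        out = m.posthoc_pairwise(df, g, omnibus, gate=0.2)
        gated_out = omnibus.index[omnibus["p"] >= 0.2]
        assert not set(out["feature_id"]) & set(gated_out)

    def test_three_groups_three_pairs(self):
        rng = np.random.default_rng(6)
        df, g = self._setup(rng)
        omnibus = m.kruskal_wallis_all(df, g)
        out = m.posthoc_pairwise(df, g, omnibus, gate=1.1)  # everything gated in
        assert (out.groupby("feature_id").size() == 3).all()

    def test_two_groups_equal_direct_wilcoxon(self):
        rng = np.random.default_rng(7)
        df, g = self._setup(rng, n_groups=2)
        omnibus = m.kruskal_wallis_all(df, g)
        out = m.posthoc_pairwise(df, g, omnibus, gate=1.1).set_index("feature_id")
        for f in out.index:
            x = df.loc[f].to_numpy()
            ref = stats.mannwhitneyu(x[:6], x[6:], alternative="two-sided").pvalue
            assert out.loc[f, "p"] == pytest.approx(ref)


class TestBlockedRankTest:
    def test_single_block_reduces_to_wilcoxon(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        g = np.array(["a"] * 10 + ["b"] * 10)
        res = m.blocked_rank_test(x, g, np.zeros(20))
        ref = stats.mannwhitneyu(x[:10], x[10:], alternative="two-sided",
                                 method="asymptotic", use_continuity=False).pvalue
        assert res.p == pytest.approx(ref, rel=1e-9)

    def test_null_calibration_with_blocks(self):
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            block = np.repeat([0, 1], 12)
            x = rng.normal(size=24) + 2.0 * block  # block effect, no group effect
            g = np.concatenate([rng.permutation(np.repeat(["a", "b"], 6)) for _ in range(2)])
            if m.blocked_rank_test(x, g, block).p < 0.05:
                rejections += 1
        assert abs(rejections / n_sim - 0.05) < 1.96 * np.sqrt(0.05 * 0.95 / n_sim) + 0.01

    def test_combining_blocks_gains_power(self):
        """A consistent within-block shift: combining two blocks of size
        n beats either single block of size n."""
        rng = np.random.default_rng(10)
        wins = 0
        for _ in range(100):
            blocks = []
            for b in range(2):
                base = rng.normal(4.0 * b, 1.0, size=12)
                base[:6] += 1.2  # group "a" shifted identically in each block
                blocks.append(base)
            x = np.concatenate(blocks)
            g = np.tile(np.repeat(["a", "b"], 6), 2)
            blk = np.repeat([0, 1], 12)
            p_comb = m.blocked_rank_test(x, g, blk).p
            p_single = min(
                m.blocked_rank_test(blocks[0], g[:12], np.zeros(12)).p,
                m.blocked_rank_test(blocks[1], g[12:], np.zeros(12)).p,
            )
            wins += p_comb < p_single
        assert wins >= 70  # clearly more powerful than single blocks

    def test_permutation_option_close_to_asymptotic(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=24)
        x[:6] += 1.0
        g = np.tile(np.repeat(["a", "b"], 6), 2)
        blk = np.repeat([0, 1], 12)
        asym = m.blocked_rank_test(x, g, blk)
        perm = m.blocked_rank_test(x, g, blk, n_permutations=2000, seed=0)
        assert perm.method == "permutation"
        assert abs(perm.p - asym.p) < 0.05

    def test_fully_degenerate_blocks_rejected(self):
        x = np.arange(8.0)
        g = np.array(["a"] * 4 + ["b"] * 4)
        blk = np.array([0, 0, 0, 0, 1, 1, 1, 1])  # each block one group only
        with pytest.raises(ValueError):
            m.blocked_rank_test(x, g, blk)


class TestSpearmanCovariates:
    def _md(self, y):
        return pd.DataFrame({"UPDRS_III": y}, index=[f"s{i}" for i in range(len(y))])

    def test_monotone_extremes(self):
        y = np.arange(8.0)
        df = pd.DataFrame([y, -y], index=["up", "down"], columns=[f"s{i}" for i in range(8)])
        res = m.spearman_covariates(df, self._md(y), covariates=("UPDRS_III",)).set_index("feature_id")
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_rho_equals_pearson_of_midranks(self):
        rng = np.random.default_rng(12)
        x = rng.integers(0, 4, size=10).astype(float)
        y = rng.integers(0, 4, size=10).astype(float)
        df = pd.DataFrame([x], index=["f"], columns=[f"s{i}" for i in range(10)])
        res = m.spearman_covariates(df, self._md(y), covariates=("UPDRS_III",))
        ref = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert res["rho"].iloc[0] == pytest.approx(ref, rel=1e-12)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="UPDRS_III"):
            m.spearman_covariates(df, self._md(np.zeros(3)), covariates=("UPDRS_III",))


class TestAlphaDiversity:
    def test_single_feature_sample(self):
        data = pd.DataFrame({"s": [100.0, 0.0]}, index=["a", "b"])
        res = m.alpha_diversity(m.CountMatrix(data=data), rarefy_depth=50, seed=0)
        assert res.loc["s", "richness"] == 1
        assert res.loc["s", "shannon"] == 0.0
        assert np.isnan(res.loc["s", "evenness"])

    def test_uniform_community(self):
        data = pd.DataFrame({"s": [50.0] * 5}, index=list("abcde"))
        res = m.alpha_diversity(m.CountMatrix(data=data), rarefy_depth=250, seed=0)
        assert res.loc["s", "shannon"] == pytest.approx(np.log(5))
        assert res.loc["s", "evenness"] == pytest.approx(1.0)

    def test_richness_is_nonzero_count(self):
        rng = np.random.default_rng(13)
        cm = random_count_matrix(rng, n_features=30, n_samples=5)
        depth = int(cm.data.sum(axis=0).min())
        res = m.alpha_diversity(cm, rarefy_depth=depth, seed=1)
        rare = m.rarefy(cm, depth, seed=1)
        for s in res.index:
            assert res.loc[s, "richness"] == (rare.data[s] > 0).sum()


class TestAccumulation:
    def test_full_depth_recovers_pooled_richness(self):
        rng = np.random.default_rng(14)
        cm = random_count_matrix(rng, n_features=20, n_samples=4)
        total = int(cm.data.sum().sum())
        res = m.accumulation_curve(cm, [total], seed=0, n_repeats=3)
        pooled_rich = int((cm.data.sum(axis=1) > 0).sum())
        assert res.loc[total, "mean_richness"] == pooled_rich

    def test_monotone_in_depth(self):
        rng = np.random.default_rng(15)
        cm = random_count_matrix(rng, n_features=40, n_samples=5)
        total = int(cm.data.sum().sum())
        depths = [total // 20, total // 5, total // 2, total]
        res = m.accumulation_curve(cm, depths, seed=2, n_repeats=10)
        assert res["mean_richness"].is_monotonic_increasing

    def test_depth_beyond_pool_rejected(self):
        data = pd.DataFrame({"s": [5.0]}, index=["a"])
        with pytest.raises(ValueError):
            m.accumulation_curve(m.CountMatrix(data=data), [10])

    def test_single_sample_matches_per_sample_rarefaction(self):
        rng = np.random.default_rng(16)
        counts = rng.integers(0, 30, size=25).astype(float)
        data = pd.DataFrame({"s": counts}, index=[f"f{i}" for i in range(25)])
        cm = m.CountMatrix(data=data)
        depth = int(counts.sum() // 2)
        acc = m.accumulation_curve(cm, [depth], seed=3, n_repeats=50)
        per_sample = np.mean([
            m.alpha_diversity(cm, depth, seed=s).loc["s", "richness"] for s in range(50)])
        assert abs(acc.loc[depth, "mean_richness"] - per_sample) < 1.5

    def test_sample_accumulation_reaches_total(self):
        rng = np.random.default_rng(17)
        cm = random_count_matrix(rng, n_features=30, n_samples=6)
        res = m.sample_accumulation(cm, seed=0, n_permutations=5)
        assert res["mean_richness"].iloc[-1] == (cm.data.sum(axis=1) > 0).sum()
        assert res["mean_richness"].is_monotonic_increasing
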
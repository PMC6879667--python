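"""Adaptive truncation: exact order-statistic sampling, the candidate-profile
null model, ART-A, and the empirical single-layer aRTP."""

import numpy as np
import pytest
from scipy import stats

from artcombine.adaptive import (
    art_a_pvalue,
    artp_adaptive_empirical,
    partial_sum_model,
    sample_sorted_head,
)
from artcombine.adaptive import _null_partial_sums, art_a_pvalue_batch, \
    single_layer_minp
from artcombine.art import art_combined, art_pvalue_batch
from artcombine.combiners import rtp_pvalue, rtp_pvalue_batch
from artcombine.pvalues import truncation_product


class TestSortedHeadSampler:
    def test_rows_nondecreasing(self, rng):
        h = sample_sorted_head(1000, 5, 30, rng)
        assert np.all(np.diff(h, axis=1) >= 0)
        assert np.all((h > 0) & (h < 1))

    @pytest.mark.parametrize("k,L", [(1, 10), (3, 10), (5, 50)])
    def test_marginal_beta_law(self, k, L):
        # P_(k) of L uniforms is Beta(k, L-k+1)
        rng = np.random.default_rng(k * 100 + L)
        h = sample_sorted_head(40_000, k, L, rng)
        assert stats.kstest(h[:, k - 1], "beta", args=(k, L - k + 1)).pvalue > 1e-3

    def test_matches_full_sort_construction(self):
        # same joint law as sorting L uniforms and keeping the k smallest
        rng = np.random.default_rng(9)
        h = sample_sorted_head(40_000, 3, 12, rng)
        full = np.sort(rng.random((40_000, 12)), axis=1)[:, :3]
        for j in range(3):
            ks = stats.ks_2samp(h[:, j], full[:, j])
            assert ks.pvalue > 1e-3


class TestPartialSumModel:
    def test_singleton_unit_model(self):
        m = partial_sum_model([7], 20, n_ref=20_000, seed=1)
        assert m.corr.shape == (1, 1)
        assert m.corr[0, 0] == pytest.approx(1.0)

    def test_unit_diagonal_and_psd(self):
        m = partial_sum_model(range(1, 8), 20, n_ref=50_000, seed=1)
        np.testing.assert_allclose(np.diag(m.corr), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(m.corr).min() > -1e-10
        assert np.all(m.corr[~np.eye(7, dtype=bool)] >= 0)

    def test_correlation_grows_with_overlap(self):
        # nested partial products share more terms as k approaches k'
        m = partial_sum_model(range(1, 11), 20, n_ref=50_000, seed=1)
        last = m.corr[:-1, -1]  # corr(k, k'=10) for k = 1..9
        assert np.all(np.diff(last) > 0)

    def test_cached(self):
        a = partial_sum_model(range(1, 4), 15, n_ref=20_000, seed=3)
        b = partial_sum_model(range(1, 4), 15, n_ref=20_000, seed=3)
        assert a is b


class TestArtA:
    def test_singleton_matches_fixed_k(self, rng):
        p = rng.random(20)
        res = art_a_pvalue(p, [5], n_ref=200_000, seed=0)
        want = art_combined(p, 5).p_combined
        assert res.p_combined == pytest.approx(want, abs=0.01)

    def test_adjusted_never_beats_best_candidate(self, rng):
        for _ in range(10):
            p = rng.random(int(rng.integers(5, 40)))
            res = art_a_pvalue(p, range(1, 6), n_ref=50_000, seed=1)
            assert res.p_combined >= res.statistic

    def test_direct_simulation_oracle(self):
        # brute force: min-P profile null from full sorts of L = 6 uniforms
        L, ks, n = 6, np.arange(1, 7), 200_000
        rng = np.random.default_rng(12)
        u = np.sort(rng.random((n, L)), axis=1)
        prof = np.column_stack([art_pvalue_batch(u, int(k)) for k in ks])
        m_null = np.sort(prof.min(axis=1))
        obs = np.array([0.01, 0.04, 0.2, 0.5, 0.7, 0.9])
        res = art_a_pvalue(obs, ks, n_ref=200_000, seed=5)
        m_obs = res.statistic
        brute = (1 + np.searchsorted(m_null, m_obs, side="right")) / (n + 1)
        se = np.sqrt(brute * (1 - brute) / n)
        assert res.p_combined == pytest.approx(brute, abs=max(3 * se * 2, 5e-3))

    def test_profile_reported(self, rng):
        res = art_a_pvalue(rng.random(15), range(1, 5), n_ref=20_000, seed=2)
        assert set(res.extra["profile"]) == {1, 2, 3, 4}
        assert res.k in {1, 2, 3, 4}

    def test_model_mismatch_raises(self, rng):
        m = partial_sum_model(range(1, 4), 10, n_ref=20_000, seed=0)
        with pytest.raises(ValueError):
            art_a_pvalue(rng.random(12), range(1, 4), model=m)


class TestEmpiricalArtp:
    def test_singleton_agrees_with_rtp(self, rng):
        p = rng.random(20)
        B = 20_000
        res = artp_adaptive_empirical(p, [3], B=B, seed=2)
        exact = rtp_pvalue(truncation_product(p, 3), 20).p_combined
        se = np.sqrt(exact * (1 - exact) / B)
        assert res.p_combined == pytest.approx(exact, abs=3 * se)

    def test_nested_oracle_small_case(self):
        # direct estimate: per-k P-values by the exact integral, min over k,
        # null law of the min from 200k fresh full sorts
        L, ks = 5, np.arange(1, 6)
        obs = np.array([0.02, 0.1, 0.3, 0.6, 0.9])
        rng = np.random.default_rng(77)
        n = 200_000
        u = np.sort(rng.random((n, L)), axis=1)
        prof = np.column_stack([
            rtp_pvalue_batch(-np.log(u[:, :k]).sum(axis=1), int(k), L)
            for k in ks
        ])
        m_null = np.sort(prof.min(axis=1))
        obs_prof = [rtp_pvalue(truncation_product(obs, int(k)), L).p_combined
                    for k in ks]
        brute = np.searchsorted(m_null, min(obs_prof), side="right") / n
        res = artp_adaptive_empirical(obs, ks, B=50_000, seed=3)
        assert res.p_combined == pytest.approx(brute, abs=0.02)

    def test_adjusted_never_beats_best_candidate(self, rng):
        p = rng.random(30)
        res = artp_adaptive_empirical(p, range(1, 11), B=2_000, seed=1)
        assert res.p_combined >= res.statistic

    def test_memory_guard(self):
        with pytest.raises(MemoryError):
            artp_adaptive_empirical(np.full(600, 0.5), range(1, 501),
                                    B=500_000_000, seed=0)

    def test_single_layer_rates_uniform(self):
        # each null row ranked against the matrix holds every level exactly
        ref = _null_partial_sums(np.arange(1, 11), 100, 20_000, seed=5)
        m = single_layer_minp(ref.partial_sums)
        adj = stats.rankdata(m, method="average") / len(m)
        for a in (0.05, 0.01, 0.005):
            assert np.mean(adj <= a) == pytest.approx(a, abs=3 * np.sqrt(
                a * (1 - a) / 20_000))

    def test_requires_minimum_B(self, rng):
        with pytest.raises(ValueError):
            artp_adaptive_empirical(rng.random(10), [2], B=10, seed=0)
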
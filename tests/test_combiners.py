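"""Rank truncated product and benchmark combiners: closed forms, the
single-integral distribution, the legacy closed form, and null calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from artcombine.combiners import (
    fisher_pvalue,
    rtp_pvalue,
    rtp_pvalue_batch,
    rtp_pvalue_legacy,
    rtp_pvalue_next,
    sidak_minp_pvalue,
    simes_pvalue,
)
from artcombine.pvalues import PValueSet, TruncationProduct, truncation_product

# Monte-Carlo oracles, frozen from 1e7 brute-force draws (sort L uniforms,
# product of k smallest <= w); quoted with their standard errors.
MC_K2_L4_W01 = (0.1721271, 0.00012)    # k=2, L=4, w=0.01
MC_K5_L20_W1E6 = (0.2049986, 0.00013)  # k=5, L=20, w=1e-6


def tp(w: float, k: int) -> TruncationProduct:
    return TruncationProduct(k=k, neg_log_w=-math.log(w))


class TestTruncationProduct:
    def test_single_element(self):
        assert truncation_product([0.5], 1).w == pytest.approx(0.5)

    def test_product_of_two(self):
        assert truncation_product([0.2, 0.1], 2).w == pytest.approx(0.02)

    def test_table8_two_smallest(self, table8):
        # hand multiplication of the two smallest reported values
        assert truncation_product(table8, 2).w == pytest.approx(
            0.0007 * 0.0941, rel=1e-12)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            truncation_product([0.5, 0.1], 3)

    def test_monotone_in_k(self, rng):
        ps = PValueSet(rng.random(12))
        ws = [truncation_product(ps, k).w for k in range(1, 13)]
        assert np.all(np.diff(ws) <= 0)


class TestRtpPvalue:
    def test_minp_closed_form(self):
        # k=1: Pr(P_(1) <= w) = 1 - (1-w)^L
        assert rtp_pvalue(tp(0.1, 1), 2).p_combined == pytest.approx(0.19, abs=1e-9)

    def test_k1_equals_sidak_grid(self, rng):
        for L in (1, 2, 5, 20, 100):
            p = rng.random(L)
            got = rtp_pvalue(truncation_product(p, 1), L).p_combined
            want = sidak_minp_pvalue(p).p_combined
            assert got == pytest.approx(want, abs=1e-10)

    def test_kL_equals_fisher(self, rng):
        for L in (1, 3, 10, 40):
            p = rng.random(L)
            got = rtp_pvalue(truncation_product(p, L), L).p_combined
            assert got == pytest.approx(fisher_pvalue(p).p_combined, abs=1e-8)

    def test_against_mc_oracle(self):
        val, se = MC_K2_L4_W01
        assert rtp_pvalue(tp(0.01, 2), 4).p_combined == pytest.approx(
            val, abs=3 * se)

    def test_monotone_in_w(self):
        ws = np.logspace(-8, -0.1, 25)
        ps = [rtp_pvalue(tp(w, 3), 10).p_combined for w in ws]
        assert np.all(np.diff(ps) >= -1e-12)

    def test_batch_matches_scalar(self):
        for k, L in [(1, 5), (2, 4), (5, 20), (10, 100), (3, 10)]:
            s = np.array([0.5, 2.0, 8.0, 20.0])
            batch = rtp_pvalue_batch(s, k, L)
            scalar = [rtp_pvalue(TruncationProduct(k, si), L).p_combined
                      for si in s]
            np.testing.assert_allclose(batch, scalar, atol=1e-6)

    def test_w_near_one_gives_one(self):
        assert rtp_pvalue(tp(0.999999, 2), 4).p_combined == pytest.approx(
            1.0, abs=1e-3)


class TestRtpNext:
    def test_kplus1_is_fisher_limit(self):
        # k+1 = L: the product of all L P-values, Fisher's case
        w = 0.1 * 0.3
        got = rtp_pvalue_next(tp(w, 1), 2).p_combined
        assert got == pytest.approx(fisher_pvalue([0.1, 0.3]).p_combined,
                                    abs=1e-8)

    def test_consistent_with_direct_kplus1(self):
        w = 1e-3
        nxt = rtp_pvalue_next(tp(w, 2), 5).p_combined
        direct = rtp_pvalue(tp(w, 3), 5).p_combined
        assert nxt == pytest.approx(direct, abs=1e-8)

    def test_w_to_one_upper_bound(self):
        assert rtp_pvalue_next(tp(1.0 - 1e-12, 1), 4).p_combined == pytest.approx(
            1.0, abs=1e-6)


class TestLegacyClosedForm:
    def test_minp_closed_form(self):
        got = rtp_pvalue_legacy(tp(0.05, 1), 3).p_combined
        assert got == pytest.approx(1 - 0.95**3, abs=1e-8)

    def test_agrees_with_integral_grid(self):
        # cross-formula equivalence on a (k, L, w) grid
        for L in (3, 5, 10, 20):
            for k in range(1, L):
                for w in (1e-6, 1e-3, 0.05, 0.5):
                    a = rtp_pvalue_legacy(tp(w, k), L).p_combined
                    b = rtp_pvalue(tp(w, k), L).p_combined
                    assert a == pytest.approx(b, abs=1e-6), (k, L, w)

    def test_against_mc_oracle(self):
        val, se = MC_K5_L20_W1E6
        assert rtp_pvalue_legacy(tp(1e-6, 5), 20).p_combined == pytest.approx(
            val, abs=3 * se)

    def test_out_of_validated_range_guard(self):
        with pytest.raises(FloatingPointError):
            rtp_pvalue_legacy(tp(1e-10, 18), 500)

    def test_moderate_k_large_w_stable(self):
        # the regime where alternating-sum evaluations collapse
        a = rtp_pvalue_legacy(tp(0.5, 7), 20).p_combined
        b = rtp_pvalue(tp(0.5, 7), 20).p_combined
        assert a == pytest.approx(b, abs=1e-7)


class TestBenchmarks:
    def test_fisher_single(self):
        assert fisher_pvalue([0.37]).p_combined == pytest.approx(0.37, abs=1e-12)

    def test_fisher_all_ones(self):
        assert fisher_pvalue([1.0, 1.0, 1.0]).p_combined == pytest.approx(
            1.0, abs=1e-9)

    def test_fisher_example(self):
        r = fisher_pvalue([0.1, 0.2])
        assert r.statistic == pytest.approx(7.824046, abs=1e-5)
        assert r.p_combined == pytest.approx(0.0982405, abs=1e-6)

    def test_simes_equal_pvalues(self):
        assert simes_pvalue([0.3, 0.3, 0.3]).p_combined == pytest.approx(0.3)

    def test_simes_single(self):
        assert simes_pvalue([0.07]).p_combined == pytest.approx(0.07)

    def test_simes_table8(self, table8):
        assert simes_pvalue(table8).p_combined == pytest.approx(0.0077, abs=1e-12)

    def test_simes_at_most_bonferroni(self, rng):
        for _ in range(50):
            p = rng.random(rng.integers(1, 30))
            assert simes_pvalue(p).p_combined <= min(len(p) * p.min(), 1.0) + 1e-12

    def test_sidak_forms(self, table8):
        assert sidak_minp_pvalue([0.05]).p_combined == pytest.approx(0.05)
        assert sidak_minp_pvalue([0.1, 0.5]).p_combined == pytest.approx(0.19)
        assert sidak_minp_pvalue(table8).p_combined == pytest.approx(
            1 - (1 - 0.0007) ** 11, rel=1e-12)


class TestNullCalibration:
    @pytest.mark.parametrize("k", [1, 2, 5])
    @pytest.mark.parametrize("L", [5, 20])
    def test_rtp_uniform_under_null(self, k, L):
        # combined P-values of 20,000 null replicates are uniform
        rng = np.random.default_rng(1000 * L + k)
        u = np.sort(rng.random((20_000, L)), axis=1)
        s = -np.log(u[:, :k]).sum(axis=1)
        p = rtp_pvalue_batch(s, k, L)
        assert stats.kstest(p, "uniform").pvalue > 0.001
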
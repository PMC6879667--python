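"""The augmented rank truncation (ART) statistic and its exact gamma null.

Like RTP, ART summarizes the k smallest of L P-values, but its null
distribution is a plain gamma — no integration. Conditional on the k-th
order statistic P_(k), the k-1 smallest P-values are iid uniform on
(0, P_(k)), so

    -ln W_{k-1} + (k-1) ln P_(k)  =  sum_{i<k} -ln( P_(i) / P_(k) )

is Gamma(k-1, 1) and independent of P_(k). P_(k) itself is Beta(k, L-k+1)
and is folded in as a third independent term by mapping it through its CDF
onto a Gamma(lambda, 1) variable, with the shape weight

    lambda = (k-1) * E[-ln P_(k)] = (k-1) * (psi(L+1) - psi(k))

chosen so the last two terms have equal expectation (a Lancaster-style
weight). The sum A_k is then exactly Gamma(k-1+lambda, 1) under the global
null, and the combined P-value is its upper tail at the observed a_k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .pvalues import CombinedResult, as_pvalue_set

__all__ = ["art_shape_lambda", "art_statistic", "art_pvalue", "art_combined",
           "art_statistic_batch", "art_pvalue_batch", "ArtComponents"]


def art_shape_lambda(k: int, L: int) -> float:
    """Gamma shape weight lambda = (k-1)(psi(L+1) - psi(k)).

    Equals (k-1) * sum_{i=k}^{L} 1/i, the expected contribution of
    -ln P_(k) scaled by the k-1 P-values below it. Zero at k = 1.
    """
    if not 1 <= k <= L:
        raise ValueError(f"need 1 <= k <= L, got k={k}, L={L}")
    return float((k - 1) * (special.digamma(L + 1) - special.digamma(k)))


@dataclass(frozen=True)
class ArtComponents:
    """Pieces of the ART statistic, kept for audit.

    ``a_k = neg_log_prod_km1 - (k-1) * neg_log_pk + gamma_term`` where
    ``gamma_term = G^{-1}_lambda(1 - B_k(p_k))``.
    """

    k: int
    L: int
    lam: float
    neg_log_prod_km1: float  # -ln W_{k-1}
    p_k: float               # k-th smallest P-value
    beta_cdf_at_pk: float    # B_k(p_k), Beta(k, L-k+1) CDF
    a_k: float


def art_statistic(pvals, k: int) -> ArtComponents:
    """Compute the ART statistic a_k from the k smallest P-values.

    Requires 2 <= k <= L; at k = 1 the statistic degenerates (lambda = 0)
    and the combined P-value is the Sidak/minimum-P form — use
    :func:`art_combined`, which routes k = 1 accordingly.
    """
    ps = as_pvalue_set(pvals)
    L = ps.L
    if not 2 <= k <= L:
        raise ValueError(f"art_statistic needs 2 <= k <= L, got k={k}, L={L}")
    lam = art_shape_lambda(k, L)
    srt = ps.sorted_values
    p_k = float(srt[k - 1])
    neg_log_prod = float(-np.log(srt[: k - 1]).sum())
    b_k = float(special.betainc(k, L - k + 1, p_k))
    # G^{-1}_lam(1 - b_k) via the inverse survival function: no cancellation
    # in 1 - b_k when p_k (hence b_k) is small.
    gamma_term = float(special.gammainccinv(lam, b_k))
    a_k = neg_log_prod + (k - 1) * math.log(p_k) + gamma_term
    return ArtComponents(
        k=k, L=L, lam=lam, neg_log_prod_km1=neg_log_prod, p_k=p_k,
        beta_cdf_at_pk=b_k, a_k=a_k,
    )


def art_pvalue(comp: ArtComponents) -> CombinedResult:
    """Combined P-value Pr(A_k >= a_k) = 1 - G_{k-1+lambda}(a_k)."""
    shape = comp.k - 1 + comp.lam
    p = float(special.gammaincc(shape, max(comp.a_k, 0.0)))
    return CombinedResult(
        method="art", p_combined=p, statistic=comp.a_k, k=comp.k,
        extra={"lambda": comp.lam, "shape": shape},
    )


def art_combined(pvals, k: int) -> CombinedResult:
    """ART combined P-value for truncation k, with the k = 1 degeneracy
    routed to the Sidak/minimum-P form (the stated k = 1 limit of RTP)."""
    ps = as_pvalue_set(pvals)
    if k == 1:
        p1 = float(ps.sorted_values[0])
        p = float(-np.expm1(ps.L * np.log1p(-p1)))
        return CombinedResult(method="art", p_combined=p, statistic=-math.log(p1),
                              k=1, extra={"lambda": 0.0, "shape": 1.0})
    return art_pvalue(art_statistic(ps, k))


def art_statistic_batch(sorted_pvals: np.ndarray, k: int,
                        L: int | None = None) -> np.ndarray:
    """Vectorized a_k over replicates.

    Parameters
    ----------
    sorted_pvals : (B, m) array
        Each row the nondecreasing m smallest P-values of a replicate
        (m = L, or any head with m >= k).
    k : int
        Truncation, 2 <= k <= m.
    L : int, optional
        Total number of tests; defaults to the row width.

    Returns
    -------
    (B,) array of ART statistic values.
    """
    B, m = sorted_pvals.shape
    L = m if L is None else L
    if not 2 <= k <= min(m, L):
        raise ValueError(f"need 2 <= k <= {min(m, L)}, got k={k}")
    lam = art_shape_lambda(k, L)
    logs = np.log(sorted_pvals[:, :k])
    p_k = sorted_pvals[:, k - 1]
    gamma_sum = (k - 1) * logs[:, -1] - logs[:, :-1].sum(axis=1)
    b_k = special.betainc(k, L - k + 1, p_k)
    return gamma_sum + special.gammainccinv(lam, b_k)


def art_pvalue_batch(sorted_pvals: np.ndarray, k: int,
                     L: int | None = None) -> np.ndarray:
    """Vectorized ART combined P-values over replicate rows (k >= 2),
    with k = 1 routed to the Sidak form."""
    L = sorted_pvals.shape[1] if L is None else L
    if k == 1:
        return -np.expm1(L * np.log1p(-sorted_pvals[:, 0]))
    a = art_statistic_batch(sorted_pvals, k, L=L)
    shape = k - 1 + art_shape_lambda(k, L)
    return special.gammaincc(shape, np.maximum(a, 0.0))
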
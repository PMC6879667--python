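"""Decorrelation by orthogonal transformation (DOT) and LD reconstruction.

Association P-values within a gene are correlated through linkage
disequilibrium (LD). If the underlying statistics are jointly
MVN(0, Sigma) under the null, the symmetric inverse square root
H = Q Lambda^{-1/2} Q^T of Sigma (from its eigendecomposition) maps them to
independent standard normals: y_e = H^T y has identity covariance. The
transformed values are converted back to P-values and fed to any combiner
built for independent tests. H is the unique symmetric root, which makes
the transform invariant to coordinate order in the equicorrelation case —
permuting the inputs permutes the outputs.

The LD correlation matrix itself can be reconstructed from haplotype
frequencies: D_ij = P_ij - p_i p_j with P_ij the di-locus frequency of both
minor alleles and p_i the minor-allele frequency, normalized to
r_ij = D_ij / sqrt(p_i(1-p_i) p_j(1-p_j)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .pvalues import PValueSet, as_pvalue_set

logger = logging.getLogger("artcombine")

__all__ = [
    "CorrelationModel",
    "orthogonal_transform",
    "decorrelate_zscores",
    "decorrelate_pvalues",
    "HaplotypeTable",
    "ld_correlation_from_haplotypes",
]

# relative eigenvalue floor; LD matrices reconstructed from haplotype
# frequencies are frequently near-singular
EIG_FLOOR_REL = 1e-10


@dataclass(frozen=True)
class CorrelationModel:
    """Eigendecomposition of a correlation matrix and its decorrelator.

    Attributes
    ----------
    sigma : (L, L) array
        The input correlation matrix.
    eigvals, eigvecs : arrays
        Eigenvalues (ascending, after flooring) and matching eigenvectors.
    transform : (L, L) array
        H = Q Lambda^{-1/2} Q^T, symmetric; H^T sigma H = I.
    floored : bool
        Whether any eigenvalue was raised to the floor.
    """

    sigma: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    transform: np.ndarray
    floored: bool = False

    @property
    def L(self) -> int:
        return self.sigma.shape[0]


def orthogonal_transform(sigma, *, strict: bool = False) -> CorrelationModel:
    """Build the DOT decorrelator H = Q Lambda^{-1/2} Q^T from Sigma.

    Parameters
    ----------
    sigma : (L, L) array-like
        Symmetric correlation matrix with unit diagonal.
    strict : bool
        If True, raise on eigenvalues below the relative floor instead of
        flooring them (default floors with a logged warning).
    """
    s = np.asarray(sigma, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("sigma must be a square matrix")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("sigma must be symmetric")
    if not np.allclose(np.diag(s), 1.0, atol=1e-8):
        raise ValueError("sigma must have unit diagonal")
    vals, vecs = np.linalg.eigh(s)
    floor = EIG_FLOOR_REL * vals[-1]
    if vals[0] < -1e-10 * max(vals[-1], 1.0):
        raise ValueError(f"sigma is not positive semidefinite (min eig {vals[0]:.3g})")
    floored = bool(vals[0] < floor)
    if floored:
        if strict:
            raise ValueError(
                f"eigenvalue {vals[0]:.3g} below floor {floor:.3g} (strict mode)"
            )
        logger.warning(
            "flooring %d eigenvalue(s) below %.3g; sigma is near-singular",
            int((vals < floor).sum()), floor,
        )
        vals = np.maximum(vals, floor)
    H = (vecs * (1.0 / np.sqrt(vals))) @ vecs.T
    return CorrelationModel(sigma=s, eigvals=vals, eigvecs=vecs, transform=H,
                            floored=floored)


def decorrelate_zscores(y, model: CorrelationModel) -> np.ndarray:
    """Apply y_e = H^T y to a vector (or rows of a matrix) of statistics."""
    y = np.asarray(y, dtype=float)
    if y.shape[-1] != model.L:
        raise ValueError(f"dimension mismatch: y has {y.shape[-1]}, model {model.L}")
    return y @ model.transform  # H symmetric, so y H == H^T y

def decorrelate_pvalues(pvals, model: CorrelationModel, *,
                        two_sided: bool = False) -> PValueSet:
    """Map correlated P-values to (null-)independent ones through DOT.

    Each P-value is converted to a normal score z = Phi^{-1}(1 - p), the
    vector is rotated by H, and the result mapped back, p_e = 1 - Phi(z_e).
    With ``two_sided=True`` the back-transform squares the rotated scores
    and uses the one-df chi-square survival instead (for P-values that were
    two-sided to begin with; the forward map then loses the sign of the
    underlying statistic, so prefer supplying signed z-scores via
    :func:`decorrelate_zscores` in that case).
    """
    ps = as_pvalue_set(pvals)
    if ps.L != model.L:
        raise ValueError(f"dimension mismatch: {ps.L} P-values, model is {model.L}")
    z = stats.norm.isf(ps.values)
    z_e = decorrelate_zscores(z, model)
    if two_sided:
        return PValueSet(stats.chi2.sf(z_e**2, 1))
    return PValueSet(stats.norm.sf(z_e))


@dataclass(frozen=True)
class HaplotypeTable:
    """Haplotypes over L biallelic SNPs ('1' = minor allele) with frequencies."""

    haplotypes: tuple
    freqs: np.ndarray = field(compare=False)

    def __init__(self, haplotypes: Sequence[str], freqs: Sequence[float]) -> None:
        haps = tuple(str(h) for h in haplotypes)
        fr = np.asarray(freqs, dtype=float)
        if len(haps) != fr.size or len(haps) == 0:
            raise ValueError("haplotypes and freqs must be nonempty and equal length")
        lens = {len(h) for h in haps}
        if len(lens) != 1:
            raise ValueError("haplotypes must have equal length")
        if any(set(h) - {"0", "1"} for h in haps):
            raise ValueError("haplotypes must be strings over {0,1}")
        if len(set(haps)) != len(haps):
            raise ValueError("haplotypes must be distinct")
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be nonnegative and sum to 1")
        object.__setattr__(self, "haplotypes", haps)
        object.__setattr__(self, "freqs", fr)

    @property
    def L(self) -> int:
        return len(self.haplotypes[0])


def ld_correlation_from_haplotypes(tab: HaplotypeTable) -> np.ndarray:
    """LD correlation matrix r from a haplotype frequency table.

    p_i sums the frequencies of haplotypes carrying the minor allele at
    locus i; P_ij those carrying it at both i and j. Raises if any locus is
    monomorphic (r undefined there).
    """
    alleles = np.array([[c == "1" for c in h] for h in tab.haplotypes], dtype=float)
    p = tab.freqs @ alleles  # minor-allele frequencies
    mono = np.flatnonzero((p <= 0.0) | (p >= 1.0))
    if mono.size:
        raise ValueError(f"monomorphic locus (index {int(mono[0])}): allele "
                         f"frequency {p[mono[0]]:.3g}")
    P2 = (alleles * tab.freqs[:, None]).T @ alleles  # di-locus frequencies
    D = P2 - np.outer(p, p)
    denom = np.sqrt(np.outer(p * (1 - p), p * (1 - p)))
    r = D / denom
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)
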
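"""Containers for P-value vectors and combined-test results.

The central object is :class:`PValueSet`, a validated vector of L P-values
from L (possibly dependent) tests of a global null hypothesis. All combiners
in this package consume a ``PValueSet`` (or anything coercible to one) and
return a :class:`CombinedResult`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("artcombine")

# P-values of exactly 0 or 1 break log-space arithmetic; clamp into the
# open interval and warn. 1e-300 stays well clear of double underflow.
CLAMP_LO = 1e-300
CLAMP_HI = 1.0 - 1e-16


def _clamp(values: np.ndarray) -> np.ndarray:
    lo = values < CLAMP_LO
    hi = values > CLAMP_HI
    if lo.any() or hi.any():
        logger.warning(
            "%d P-value(s) clamped into [%g, %g] for log-space arithmetic",
            int(lo.sum() + hi.sum()), CLAMP_LO, CLAMP_HI,
        )
        values = np.clip(values, CLAMP_LO, CLAMP_HI)
    return values


@dataclass(frozen=True)
class PValueSet:
    """A vector of L P-values in (0, 1], with a cached sorted view.

    Parameters
    ----------
    values : array-like of float
        One P-value per test. Values of exactly 0 or 1 are clamped to the
        open interval (with a logged warning); anything outside [0, 1] or
        non-finite raises ``ValueError``.
    """

    values: np.ndarray
    sorted_values: np.ndarray = field(init=False, repr=False, compare=False)

    def __init__(self, values: Sequence[float]) -> None:
        arr = np.atleast_1d(np.asarray(values, dtype=float))
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("need a one-dimensional, nonempty vector of P-values")
        if not np.all(np.isfinite(arr)):
            raise ValueError("P-values must be finite")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            bad = int(np.flatnonzero((arr < 0) | (arr > 1))[0])
            raise ValueError(f"P-value out of [0, 1] at position {bad}: {arr[bad]}")
        arr = _clamp(arr)
        object.__setattr__(self, "values", arr)
        # stable sort: ties keep input order, irrelevant for products
        object.__setattr__(self, "sorted_values", np.sort(arr, kind="stable"))

    def __len__(self) -> int:
        return self.values.size

    @property
    def L(self) -> int:
        return self.values.size


def as_pvalue_set(pvals) -> PValueSet:
    return pvals if isinstance(pvals, PValueSet) else PValueSet(pvals)


@dataclass(frozen=True)
class TruncationProduct:
    """Product of the k smallest P-values, kept on the -log scale.

    ``neg_log_w`` = -ln Π_{i<=k} P_(i), accumulated as a sum of logs so
    that very small products do not underflow.
    """

    k: int
    neg_log_w: float

    @property
    def w(self) -> float:
        return math.exp(-self.neg_log_w)


def truncation_product(pvals, k: int) -> TruncationProduct:
    """Product of the ``k`` smallest P-values of the set.

    Parameters
    ----------
    pvals : PValueSet or array-like
    k : int
        Truncation point, 1 <= k <= L.
    """
    ps = as_pvalue_set(pvals)
    if not 1 <= k <= ps.L:
        raise ValueError(f"truncation point k={k} out of range [1, {ps.L}]")
    neg_log_w = float(-np.log(ps.sorted_values[:k]).sum())
    return TruncationProduct(k=int(k), neg_log_w=neg_log_w)


@dataclass(frozen=True)
class CombinedResult:
    """Outcome of a combined P-value test.

    Attributes
    ----------
    method : str
        Label of the combiner ("rtp", "art", "fisher", ...).
    p_combined : float
        The combined P-value for the global null, in [0, 1].
    statistic : float
        The test statistic on its natural scale (e.g. -ln W_k for RTP,
        a_k for ART, the min-P for adaptive methods).
    k : int or None
        Truncation point used, if the method truncates.
    extra : dict
        Method-specific audit fields (e.g. the ART shape weight lambda,
        the per-k P-value profile of adaptive methods).
    """

    method: str
    p_combined: float
    statistic: float = math.nan
    k: Optional[int] = None
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not (0.0 <= self.p_combined <= 1.0 or math.isnan(self.p_combined)):
            raise ValueError(f"combined P-value {self.p_combined} outside [0, 1]")
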
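"""Exact combinatorial statistics for enrichment testing.

Everything here is computed in log-gamma space so that genome-scale
margins (tens of thousands of genes or TE loci) never overflow:

* :func:`hypergeom_upper_tail` — P(X >= k) for a hypergeometric draw,
  the region-enrichment statistic (k DE TE loci among n loci in a genic
  region, drawn from a genome with K DE loci out of N).
* :func:`fisher_exact_two_sided` — the 2x2 exact test linking "targeted
  by a DE small RNA" with "differentially expressed".
* :func:`bh_adjust` — Benjamini–Hochberg step-up FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .errors import ContractError

__all__ = [
    "HypergeomQuery",
    "ContingencyTable",
    "hypergeom_upper_tail",
    "fisher_exact_two_sided",
    "bh_adjust",
]

#: relative slack when comparing point probabilities in the two-sided
#: Fisher sum; absorbs floating-point rounding of log-space terms.
POINT_PROB_RTOL = 1e-7


def _log_comb(n, k):
    """log C(n, k), vectorised; exact via lgamma for integer arguments."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


@dataclass(frozen=True)
class HypergeomQuery:
    """Parameters of an upper-tail hypergeometric question.

    k observed successes in a draw of size n from a population of N
    containing K successes.  k may exceed min(n, K) only to express the
    degenerate "impossible event" whose tail probability is 0.
    """

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        for name in ("k", "n", "K", "N"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ContractError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ContractError(f"{name} must be non-negative, got {v}")
        if self.n > self.N:
            raise ContractError(f"draw size n={self.n} exceeds population N={self.N}")
        if self.K > self.N:
            raise ContractError(f"successes K={self.K} exceed population N={self.N}")


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Summed in log space over the support i = max(k, n-(N-K)) .. min(n, K);
    returns 1.0 for k <= 0 and 0.0 when k lies above the support.
    """
    q = HypergeomQuery(int(k), int(n), int(K), int(N))
    if q.k <= 0:
        return 1.0
    hi = min(q.n, q.K)
    if q.k > hi:
        return 0.0
    lo = max(q.k, q.n - (q.N - q.K))
    i = np.arange(lo, hi + 1)
    log_terms = (
        _log_comb(q.K, i) + _log_comb(q.N - q.K, q.n - i) - _log_comb(q.N, q.n)
    )
    m = log_terms.max()
    total = float(np.exp(m) * np.exp(log_terms - m).sum())
    return min(1.0, total)


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table with its sample odds ratio and two-sided Fisher p.

    Layout: rows = targeted yes/no, columns = DE yes/no, so ``a`` is the
    in-both cell.  ``odds_ratio`` is the cross-product ratio a*d / (b*c):
    +inf when b*c == 0 with a*d > 0, and nan (``odds_ratio_defined`` is
    False) when both products vanish.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio_defined(self) -> bool:
        return not np.isnan(self.odds_ratio)


def _cross_product_or(a: int, b: int, c: int, d: int, haldane: bool) -> float:
    if haldane:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    ad, bc = a * d, b * c
    if bc > 0:
        return ad / bc
    return float("inf") if ad > 0 else float("nan")


def fisher_exact_two_sided(
    a: int, b: int, c: int, d: int, haldane: bool = False
) -> ContingencyTable:
    """Two-sided Fisher exact test by the point-probability method.

    Sums the probabilities of every table sharing the observed margins
    whose point probability does not exceed the observed one (within
    relative tolerance :data:`POINT_PROB_RTOL`).  ``haldane`` switches
    the reported odds ratio to the +0.5-corrected (Haldane–Anscombe)
    variant; the p-value is unaffected.
    """
    cells = (a, b, c, d)
    for v in cells:
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v < 0:
            raise ContractError(f"cell counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        raise ContractError("all-zero 2x2 table has no defined test")
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    i = np.arange(lo, hi + 1)
    log_p = _log_comb(r1, i) + _log_comb(r2, c1 - i) - _log_comb(n, c1)
    log_obs = float(log_p[a - lo])
    keep = log_p <= log_obs + np.log1p(POINT_PROB_RTOL)
    m = log_p.max()
    p = float(np.exp(m) * np.exp(log_p[keep] - m).sum())
    return ContingencyTable(
        a, b, c, d, _cross_product_or(a, b, c, d, haldane), min(1.0, p)
    )


def bh_adjust(raw: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    adjusted_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values,
    capped at 1, returned in the input order.
    """
    p = np.asarray(raw, dtype=float)
    if p.ndim != 1:
        raise ContractError("bh_adjust expects a 1-D sequence of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ContractError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m, dtype=float)
    out[order] = adjusted_sorted
    return out
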
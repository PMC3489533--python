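"""Shared hypergeometric machinery.

Every statistic in the toolbox reduces to the same sampling-without-replacement
model: a universe of ``N`` objects carries ``R`` "marked" ones, a subset of
size ``n`` is drawn, and ``r`` marked objects land in the draw.  Under the
null hypothesis that the subset and the marking are unrelated, ``r`` follows
the hypergeometric distribution

    p(r, n, R, N) = C(R, r) * C(N - R, n - r) / C(N, n)

with mean ``mu = n * R / N`` and variance
``sigma^2 = n * q * (1 - q) * (1 - (n - 1)/(N - 1))`` where ``q = R / N``.
Enrichment and connectivity p-values are upper-tail sums of this pmf;
fragment prioritization uses the z-score ``(r - mu) / sigma``.

All tail sums are computed exactly in log space (log-gamma binomials); the
normal approximation is never substituted for a p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentCounts",
    "HypergeomSummary",
    "hypergeom_pmf",
    "upper_tail_pvalue",
    "lower_tail_pvalue",
    "hypergeom_summary",
    "bh_fdr",
]

#: conventional significance threshold for a single test
DEFAULT_ALPHA = 0.05
#: default level at which the BH procedure controls the FDR
DEFAULT_FDR_LEVEL = 0.05


@dataclass(frozen=True)
class EnrichmentCounts:
    """The (r, n, R, N) quadruple every hypergeometric computation consumes.

    r : size of the intersection (marked objects in the draw)
    n : size of the drawn subset
    R : number of marked objects in the universe
    N : universe size
    """

    r: int
    n: int
    R: int
    N: int

    def __post_init__(self) -> None:
        violations = []
        if self.N < 1:
            violations.append(f"N >= 1 (got N={self.N})")
        if not (0 <= self.n <= self.N):
            violations.append(f"0 <= n <= N (got n={self.n}, N={self.N})")
        if not (0 <= self.R <= self.N):
            violations.append(f"0 <= R <= N (got R={self.R}, N={self.N})")
        lo = max(0, self.R + self.n - self.N)
        hi = min(self.n, self.R)
        if not (lo <= self.r <= hi):
            violations.append(
                f"max(0, R+n-N) <= r <= min(n, R) (got r={self.r}, "
                f"bounds [{lo}, {hi}])"
            )
        if violations:
            raise ValueError(
                "invalid hypergeometric counts: " + "; ".join(violations)
            )

    @property
    def support(self) -> range:
        """Attainable values of r for these (n, R, N)."""
        return range(max(0, self.R + self.n - self.N), min(self.n, self.R) + 1)


@dataclass(frozen=True)
class HypergeomSummary:
    """Moments and z-score of the null distribution for one set of counts."""

    mu: float
    sigma2: float
    q: float
    z: float | None  # None when sigma == 0 (degenerate distribution)


def _log_binom(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _log_pmf(r: int, n: int, R: int, N: int) -> float:
    return _log_binom(R, r) + _log_binom(N - R, n - r) - _log_binom(N, n)


def hypergeom_pmf(c: EnrichmentCounts) -> float:
    """Exact point probability p(r, n, R, N), computed in log space."""
    return float(math.exp(_log_pmf(c.r, c.n, c.R, c.N)))


def upper_tail_pvalue(c: EnrichmentCounts) -> float:
    """Cumulative probability of observing ``r`` or more marked objects.

    This is the enrichment / over-connectivity p-value: the sum of the pmf
    from ``r`` to ``min(n, R)``.  ``r = 0`` always yields 1.
    """
    if c.r <= max(0, c.R + c.n - c.N):
        return 1.0  # tail covers the whole support
    logs = [_log_pmf(i, c.n, c.R, c.N) for i in range(c.r, min(c.n, c.R) + 1)]
    if not logs:
        return 0.0
    m = max(logs)
    total = m + math.log(sum(math.exp(x - m) for x in logs))
    return float(min(1.0, math.exp(total)))


def lower_tail_pvalue(c: EnrichmentCounts, literal_paper_mode: bool = False) -> float:
    """Under-connectivity probability.

    The exact lower tail is P(X <= r).  ``literal_paper_mode`` instead
    returns ``1 - P(X >= r)``, the complement-of-the-upper-tail convention
    some legacy reports print; the two differ by the pmf mass at r.
    """
    if literal_paper_mode:
        return float(max(0.0, 1.0 - upper_tail_pvalue(c)))
    if c.r >= min(c.n, c.R):
        return 1.0  # tail covers the whole support
    lo = max(0, c.R + c.n - c.N)
    logs = [_log_pmf(i, c.n, c.R, c.N) for i in range(lo, c.r + 1)]
    m = max(logs)
    total = m + math.log(sum(math.exp(x - m) for x in logs))
    return float(min(1.0, math.exp(total)))


def hypergeom_summary(c: EnrichmentCounts) -> HypergeomSummary:
    """Mean, variance, marked fraction and z-score for one set of counts.

    z is ``None`` when the null distribution is degenerate (sigma = 0, e.g.
    R = 0, R = N, n = 0 or n = N): no deviation from expectation is possible.
    """
    q = c.R / c.N
    mu = c.n * q
    if c.N == 1:
        sigma2 = 0.0
    else:
        sigma2 = c.n * q * (1.0 - q) * (1.0 - (c.n - 1) / (c.N - 1))
    sigma2 = max(0.0, sigma2)
    z = (c.r - mu) / math.sqrt(sigma2) if sigma2 > 0 else None
    return HypergeomSummary(mu=mu, sigma2=sigma2, q=q, z=z)


def bh_fdr(pvalues: Sequence[float] | Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; ties receive identical q-values; q >= p
    elementwise and q <= 1.  Controls the FDR at any level alpha when
    findings with q <= alpha are called significant.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
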
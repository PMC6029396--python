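"""Shared statistical primitives: Poisson tails, eligibility thresholds,
Benjamini-Hochberg FDR, ECDFs and the two-sample Kolmogorov-Smirnov test.

Every cohort comparison in the pipeline reduces to an ECDF contrast scored by
the two-sample KS statistic, so these live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats as sps


def poisson_sf(c: int, lam: float) -> float:
    """Upper tail P(X >= c) for X ~ Poisson(lam).

    Computed through the regularized incomplete gamma function (stable for the
    very small per-window rates a 200-bp window produces).
    """
    if c < 0 or lam < 0:
        raise ValueError(f"poisson_sf requires c >= 0 and lam >= 0, got c={c}, lam={lam}")
    if c == 0:
        return 1.0
    # P(X >= c) = sf(c - 1)
    return float(sps.poisson.sf(c - 1, lam))


def min_eligible_count(lam: float, p0: float) -> int:
    """Smallest integer c with poisson_sf(c, lam) < p0.

    This is the window-eligibility threshold: a window needs at least this many
    tags before it can seed or extend an enriched island.
    """
    if not (0 < p0 <= 1):
        raise ValueError(f"p0 must be in (0, 1], got {p0}")
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    c = 0
    while poisson_sf(c, lam) >= p0:
        c += 1
        if c > 10_000_000:  # unreachable for sane rates
            raise RuntimeError("min_eligible_count failed to converge")
    return c


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class Ecdf:
    """Empirical CDF F(x) = #(values <= x) / n over a fixed sample."""

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("Ecdf requires a non-empty sample")
        self.values = np.sort(v)
        self.n = v.size

    def __call__(self, x):
        return np.searchsorted(self.values, np.asarray(x, dtype=float),
                               side="right") / self.n

    def table(self) -> np.ndarray:
        """(x, F(x)) pairs at the sample's sorted values."""
        return np.column_stack([self.values, np.arange(1, self.n + 1) / self.n])


@dataclass(frozen=True)
class KsResult:
    """Two-sample KS outcome: sup-norm distance, asymptotic p, and direction.

    ``direction`` is the sign of F_a - F_b at the point of maximal absolute
    difference: +1 means sample a's ECDF lies above (a is stochastically
    smaller), -1 the reverse, 0 when D = 0.
    """

    d: float
    p_value: float
    direction: int

    def __post_init__(self):
        if not 0 <= self.d <= 1:
            raise ValueError(f"D must be in [0, 1], got {self.d}")


def ks_two_sample(a, b) -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the exact sup over pooled sample points of \\|F_a - F_b\\|; the p-value
    uses the asymptotic Kolmogorov distribution evaluated at sqrt(n_eff) * D
    with n_eff = n_a n_b / (n_a + n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires two non-empty samples")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    diff = fa - fb
    i = int(np.argmax(np.abs(diff)))
    d = float(abs(diff[i]))
    direction = int(np.sign(diff[i])) if d > 0 else 0
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(n_eff) * d)) if d > 0 else 1.0
    return KsResult(d=d, p_value=min(p, 1.0), direction=direction)
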
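"""Shared exact-test statistics: Fisher 2x2, odds ratios, Woolf CIs, BH, Spearman.

Every enrichment in the package (genomic features, motifs, gene sets) reduces
to a 2x2 table summarised by :class:`EnrichmentResult`, so the arithmetic
lives here in one place.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "EnrichmentResult",
    "fisher_exact_2x2",
    "odds_ratio_woolf",
    "bh_adjust",
    "enrichment_result",
    "finalize_q",
    "spearman_with_p",
]

# Relative tolerance for pmf ties in the two-sided Fisher sum. Tables that are
# mathematically tied can differ in the last float bits; anything closer than
# this is treated as tied.
_TIE_RTOL = 1e-7

Z_95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class EnrichmentResult:
    """2x2 enrichment summary: counts, odds ratio, 95% Woolf CI, Fisher p, BH q.

    Cells follow the (query-in, query-out, background-in, background-out)
    convention: ``a`` query hits, ``b`` query misses, ``c`` background hits,
    ``d`` background misses.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    p: float = field(init=False)
    q: float = float("nan")

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("2x2 cells must be non-negative")
        self.odds_ratio, self.ci_low, self.ci_high = odds_ratio_woolf(
            self.a, self.b, self.c, self.d
        )
        self.p = fisher_exact_2x2(self.a, self.b, self.c, self.d)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's (up to a relative
    float tolerance for ties).
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1 = a + b
    r2 = c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    xs = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(xs, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def odds_ratio_woolf(
    a: float, b: float, c: float, d: float, z: float = Z_95
) -> tuple[float, float, float]:
    """Odds ratio with Woolf (log-normal) confidence interval.

    Applies the Haldane-Anscombe +0.5 correction to *all four* cells whenever
    any cell is zero, which keeps the estimate and CI finite.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsr = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = math.log(oddsr)
    return oddsr, math.exp(log_or - z * se), math.exp(log_or + z * se)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1, via the standard
    reverse-cummin formulation. NaN inputs are rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrichment_result(label: str, a: int, b: int, c: int, d: int) -> EnrichmentResult:
    return EnrichmentResult(label=label, a=a, b=b, c=c, d=d)


def finalize_q(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Assign BH q-values across a family of enrichment results, in place."""
    if not results:
        return results
    qs = bh_adjust([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho (n <= 10)."""
    n = rx.size
    cx = (rx - rx.mean()) / (rx.std() * math.sqrt(n))
    cy = ry - ry.mean()
    sy = cy.std() * math.sqrt(n)
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    perms = itertools.permutations(cy.tolist())
    chunk_size = 200_000
    while True:
        chunk = list(itertools.islice(perms, chunk_size))
        if not chunk:
            break
        mat = np.asarray(chunk)
        rhos = (mat @ cx) / sy
        count += int((np.abs(rhos) >= target).sum())
        total += mat.shape[0]
    return count / total


def spearman_with_p(x, y) -> tuple[float, float]:
    """Spearman rho with exact permutation p for n <= 10, asymptotic otherwise.

    Returns (nan, nan) when either input has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = x.size
    if n < 2:
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        # t approximation, as used by scipy.stats.spearmanr
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)
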
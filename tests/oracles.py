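"""Independent brute-force oracles used to verify the package's statistics.

These deliberately avoid the code paths they check: exact rational
hypergeometric enumeration for Fisher, a definitional O(m^2) BH, and
union-find single linkage for DMR chaining.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational enumeration over fixed margins."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    total = sum(p for p in probs.values() if p <= p_obs)
    return float(min(total, Fraction(1)))


def odds_ratio_oracle(a, b, c, d) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def bh_oracle(pvalues) -> np.ndarray:
    """Definitional BH: q_i = min over {j: p_j >= p_i} of p_j * m / rank(p_j),
    rank(p_j) = #{k: p_k <= p_j}, capped at 1. O(m^2) via broadcasting."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    rank = (p[None, :] >= p[:, None]).sum(axis=0)  # rank[j] = #{k: p_k <= p_j}
    vals = p * m / rank
    ge = p[None, :] >= p[:, None]  # ge[i, j]: p_j >= p_i
    big = np.where(ge, vals[None, :], np.inf)
    return np.minimum(big.min(axis=1), 1.0)


def single_linkage_oracle(positions, deltas, max_gap: int, min_sites: int):
    """O(n^2) union-find single linkage at the gap cutoff; returns regions as
    (start, end, sorted member positions, direction) tuples."""
    positions = list(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    regions = []
    for members in groups.values():
        if len(members) < min_sites:
            continue
        pos = sorted(positions[i] for i in members)
        ds = [deltas[i] for i in members]
        if all(d > 0 for d in ds):
            direction = "hyper"
        elif all(d < 0 for d in ds):
            direction = "hypo"
        else:
            direction = "mixed"
        regions.append((pos[0], pos[-1] + 2, tuple(pos), direction))
    return sorted(regions)
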
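"""Per-CpG differential methylation: collapse, filter, test, adjust, call.

The atom is a CpG dyad with per-sample methylated/unmethylated read counts.
Counts are float arrays with NaN meaning "absent" (site not observed in that
sample) — absent is never imputed to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust, fisher_exact_2x2

__all__ = [
    "MethylomeTable",
    "ConcordanceResult",
    "collapse_and_filter",
    "test_dm",
    "call_dm",
    "concordance_r2",
]

CONDITIONS = ("uncut", "cut")


@dataclass
class MethylomeTable:
    """Site table plus aligned per-sample count matrices.

    ``sites`` has columns chrom, pos (0-based), strand and, after collapsing,
    ``one_sided``. ``meth``/``unmeth`` are float (n_sites, n_samples) arrays.
    """

    sites: pd.DataFrame
    meth: np.ndarray
    unmeth: np.ndarray
    samples: list[str]
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if self.meth.shape != self.unmeth.shape:
            raise ValueError("meth/unmeth shape mismatch")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count matrix shape does not match sites x samples")
        unknown = set(self.conditions.values()) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        missing = [s for s in self.samples if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.meth, initial=0) < 0 or np.nanmin(self.unmeth, initial=0) < 0:
                raise ValueError("negative counts")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    def condition_columns(self, condition: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if self.conditions[s] == condition]

    def mean_coverage(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.coverage(), axis=1)


def collapse_and_filter(
    table: MethylomeTable, min_cov: int = 5, scope: str = "every-sample"
) -> MethylomeTable:
    """Collapse +/- strand records of each dyad and apply the coverage filter.

    A '-' record at position p+1 is summed into its '+' partner at p; the
    merged record sits at p. A '-' record with no partner keeps its own
    position and is flagged ``one_sided`` (as is an unpartnered '+'). Sites
    are retained iff total coverage >= ``min_cov`` — in every sample
    (``scope="every-sample"``, the default and stricter reading) or summed
    over samples (``scope="pooled"``).
    """
    if scope not in ("every-sample", "pooled"):
        raise ValueError(f"unknown coverage scope {scope!r}")
    if min_cov < 0:
        raise ValueError("min_cov must be non-negative")

    sites = table.sites.reset_index(drop=True)
    strand = sites["strand"].to_numpy()
    pos = sites["pos"].to_numpy(dtype=np.int64)
    # anchor: '-' records belong to the dyad anchored one bp to the left
    anchor = np.where(strand == "-", pos - 1, pos)
    key = pd.DataFrame({"chrom": sites["chrom"], "anchor": anchor})
    grouped = key.groupby(["chrom", "anchor"], sort=True).indices

    n_samples = len(table.samples)
    out_rows = []
    meth_rows = np.empty((len(grouped), n_samples))
    unmeth_rows = np.empty((len(grouped), n_samples))
    for r, ((chrom, a), idx) in enumerate(sorted(grouped.items())):
        idx = np.asarray(idx)
        has_plus = (strand[idx] != "-").any()
        has_minus = (strand[idx] == "-").any()
        if has_plus:
            at = int(a)
            one_sided = not has_minus
        else:
            # unpartnered '-' record keeps its own (G) position
            at = int(pos[idx[0]])
            one_sided = True
        m = table.meth[idx]
        u = table.unmeth[idx]
        all_nan_m = np.isnan(m).all(axis=0)
        all_nan_u = np.isnan(u).all(axis=0)
        with np.errstate(invalid="ignore"):
            msum = np.nansum(m, axis=0)
            usum = np.nansum(u, axis=0)
        msum[all_nan_m] = np.nan
        usum[all_nan_u] = np.nan
        meth_rows[r] = msum
        unmeth_rows[r] = usum
        out_rows.append((chrom, at, ".", one_sided))

    out_sites = pd.DataFrame(out_rows, columns=["chrom", "pos", "strand", "one_sided"])
    cov = meth_rows + unmeth_rows
    if scope == "every-sample":
        with np.errstate(invalid="ignore"):
            keep = np.all(~np.isnan(cov) & (cov >= min_cov), axis=1)
    else:
        with np.errstate(invalid="ignore"):
            total = np.nansum(cov, axis=1)
        keep = total >= min_cov
    return MethylomeTable(
        sites=out_sites[keep].reset_index(drop=True),
        meth=meth_rows[keep],
        unmeth=unmeth_rows[keep],
        samples=list(table.samples),
        conditions=dict(table.conditions),
    )


def _pooled_counts(table: MethylomeTable, condition: str) -> tuple[np.ndarray, np.ndarray]:
    cols = table.condition_columns(condition)
    if not cols:
        raise ValueError(f"no samples in condition {condition!r}")
    with np.errstate(invalid="ignore"):
        m = np.nansum(table.meth[:, cols], axis=1)
        u = np.nansum(table.unmeth[:, cols], axis=1)
    return m, u


def _binom_loglik(m: float, n: float, p: float) -> float:
    if n == 0:
        return 0.0
    ll = 0.0
    if m > 0:
        ll += m * math.log(p)
    if n - m > 0:
        ll += (n - m) * math.log1p(-p)
    return ll


def _logistic_lrt_p(mu: float, uu: float, mc: float, uc: float) -> float:
    """LR test of condition effect in a binomial model of methylation.

    A saturated-in-condition logistic model has closed-form MLEs (the pooled
    per-condition proportions), so no iterative fit is needed.
    """
    n1, n2 = mu + uu, mc + uc
    p1, p2 = mu / n1, mc / n2
    p0 = (mu + mc) / (n1 + n2)
    ll_full = _binom_loglik(mu, n1, p1) + _binom_loglik(mc, n2, p2)
    ll_null = _binom_loglik(mu, n1, p0) + _binom_loglik(mc, n2, p0)
    stat = max(0.0, 2.0 * (ll_full - ll_null))
    return float(sps.chi2.sf(stat, df=1))


def test_dm(table: MethylomeTable, method: str = "pooled-fisher") -> pd.DataFrame:
    """Per-site delta (percentage points) and two-sided p-value.

    delta_pp = 100 * pooled cut fraction - 100 * pooled uncut fraction.
    Sites with zero pooled coverage in either condition are excluded
    (p = NaN, reason = 'zero_coverage').
    """
    if method not in ("pooled-fisher", "logistic-lrt"):
        raise ValueError(f"unknown method {method!r}")
    m_uncut, u_uncut = _pooled_counts(table, "uncut")
    m_cut, u_cut = _pooled_counts(table, "cut")
    tot_uncut = m_uncut + u_uncut
    tot_cut = m_cut + u_cut

    ok = (tot_uncut > 0) & (tot_cut > 0)
    delta = np.full(table.n_sites, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta[ok] = 100.0 * m_cut[ok] / tot_cut[ok] - 100.0 * m_uncut[ok] / tot_uncut[ok]

    p = np.full(table.n_sites, np.nan)
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in np.flatnonzero(ok):
        key = (int(m_uncut[i]), int(u_uncut[i]), int(m_cut[i]), int(u_cut[i]))
        pv = cache.get(key)
        if pv is None:
            if method == "pooled-fisher":
                pv = fisher_exact_2x2(*key)
            else:
                pv = _logistic_lrt_p(*key)
            cache[key] = pv
        p[i] = pv

    out = table.sites[["chrom", "pos"]].copy()
    out["delta_pp"] = delta
    out["p"] = p
    out["reason"] = np.where(ok, "", "zero_coverage")
    return out


def call_dm(
    tests: pd.DataFrame, q_threshold: float = 0.05, delta_threshold: float = 20.0
) -> tuple[pd.DataFrame, dict]:
    """BH-adjust tested sites and flag DM: q < q_threshold AND |delta| > delta_threshold.

    Returns the augmented table (q, is_dm columns) and a summary dict with
    counts of tested, DM, hyper- (delta > 0) and hypomethylated sites.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError("q_threshold must lie in (0, 1]")
    if not 0 <= delta_threshold < 100:
        raise ValueError("delta_threshold must lie in [0, 100)")
    out = tests.copy()
    tested = out["p"].notna().to_numpy()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    delta = out["delta_pp"].to_numpy()
    with np.errstate(invalid="ignore"):
        is_dm = tested & (q < q_threshold) & (np.abs(delta) > delta_threshold)
    out["is_dm"] = is_dm
    summary = {
        "n_tested": int(tested.sum()),
        "n_dm": int(is_dm.sum()),
        "n_hyper": int((is_dm & (delta > 0)).sum()),
        "n_hypo": int((is_dm & (delta < 0)).sum()),
    }
    return out, summary


@dataclass
class ConcordanceResult:
    r2: float
    n: int


def concordance_r2(a: dict, b: dict) -> ConcordanceResult:
    """Squared Pearson correlation of methylation percentages at shared sites."""
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared sites, got {len(shared)}")
    x = np.asarray([a[k] for k in shared], dtype=float)
    y = np.asarray([b[k] for k in shared], dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the percentage vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    return ConcordanceResult(r2=r * r, n=len(shared))
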
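"""Genomic-feature context for CpG sites and enrichment statistics.

Feature precedence is promoter > exon > intron > enhancer > cpg_island >
intergenic; enhancer overlap is additionally reported orthogonally because
enhancers frequently sit inside introns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bundle import AnnotationBundle
from .intervals import GenomicIntervals, gene_tss, nearest_tss
from .stats import EnrichmentResult, finalize_q

__all__ = [
    "FEATURE_LABELS",
    "assign_features",
    "tss_distance_bins",
    "coverage_matched_background",
    "feature_enrichment",
    "enhancer_proximity",
    "DEFAULT_TSS_BINS",
]

FEATURE_LABELS = ["promoter", "exon", "intron", "enhancer", "cpg_island", "intergenic"]

DEFAULT_TSS_BINS = [0, 1_000, 10_000, 100_000, 500_000]


def _promoter_intervals(genes: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Strand-aware promoter windows: signed TSS distance in [window0, window1)."""
    up, down = window
    tss = gene_tss(genes)
    plus = tss["strand"] == "+"
    start = np.where(plus, tss["tss"] + up, tss["tss"] - down + 1)
    end = np.where(plus, tss["tss"] + down, tss["tss"] - up + 1)
    return pd.DataFrame(
        {"chrom": tss["chrom"], "start": np.maximum(start, 0), "end": np.maximum(end, 0)}
    )


def assign_features(
    sites: pd.DataFrame,
    bundle: AnnotationBundle,
    promoter_window: tuple[int, int] = (-1500, 500),
) -> pd.DataFrame:
    """Primary feature label, enhancer overlap flag, and nearest-TSS context.

    Sites on chromosomes absent from the annotation are labelled intergenic
    (counted in the ``n_unknown_chrom`` attribute on the result).
    """
    if promoter_window[0] >= promoter_window[1]:
        raise ValueError("promoter window must be a non-empty signed range")
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy(dtype=np.int64)
    n = pos.size

    known = np.isin(chroms, list(bundle.chrom_sizes))
    promoters = GenomicIntervals(_promoter_intervals(bundle.genes, promoter_window))
    exons = GenomicIntervals(bundle.exons[["chrom", "start", "end"]])
    gene_bodies = GenomicIntervals(bundle.genes[["chrom", "start", "end"]])
    enhancers = GenomicIntervals(bundle.enhancers)
    islands = GenomicIntervals(bundle.cpg_islands)

    in_promoter = promoters.contains(chroms, pos)
    in_exon = exons.contains(chroms, pos)
    in_gene = gene_bodies.contains(chroms, pos)
    in_enhancer = enhancers.contains(chroms, pos)
    in_island = islands.contains(chroms, pos)

    label = np.full(n, "intergenic", dtype=object)
    label[in_island] = "cpg_island"
    label[in_enhancer] = "enhancer"
    label[in_gene & ~in_exon] = "intron"
    label[in_exon] = "exon"
    label[in_promoter] = "promoter"

    gene_ids, signed = nearest_tss(chroms, pos, gene_tss(bundle.genes))
    orientation = np.where(signed < 0, "upstream", "downstream")
    orientation = np.where(pd.isna(signed), "", orientation)

    out = sites[["chrom", "pos"]].copy().reset_index(drop=True)
    out["primary_label"] = label
    out["enhancer_overlap"] = in_enhancer
    out["tss_distance"] = signed
    out["nearest_gene"] = gene_ids
    out["orientation"] = orientation
    out.attrs["n_unknown_chrom"] = int((~known).sum())
    return out


def tss_distance_bins(
    assignments: pd.DataFrame, bin_edges: list[int] | None = None
) -> pd.DataFrame:
    """Histogram of |TSS distance| by (bin, orientation). Counts sum to n sites."""
    edges = list(bin_edges) if bin_edges is not None else list(DEFAULT_TSS_BINS)
    if sorted(edges) != edges or len(edges) < 1:
        raise ValueError("bin edges must be sorted")
    d = assignments["tss_distance"].to_numpy(dtype=float)
    if np.isnan(d).all():
        raise ValueError("no TSS distances available (empty gene set?)")
    full_edges = np.asarray(edges + [np.inf], dtype=float)
    labels = [
        f"[{int(a)},{int(b)})" if np.isfinite(b) else f"[{int(a)},inf)"
        for a, b in zip(full_edges[:-1], full_edges[1:])
    ]
    idx = np.searchsorted(full_edges, np.abs(d), side="right") - 1
    rows = []
    for b, lab in enumerate(labels):
        for orient in ("upstream", "downstream"):
            mask = (idx == b) & (assignments["orientation"].to_numpy() == orient)
            rows.append({"bin": lab, "orientation": orient, "count": int(mask.sum())})
    return pd.DataFrame(rows)


def coverage_matched_background(
    dm_index,
    all_tested: pd.DataFrame,
    n_strata: int = 10,
    multiplier: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Sample a background matched to the DM sites' coverage distribution.

    ``all_tested`` needs a ``coverage`` column; ``dm_index`` indexes rows of
    ``all_tested`` that are the query. Sites are binned into ``n_strata``
    coverage quantiles and the background is drawn without replacement from
    the non-query sites, matching the query's stratum proportions at
    ``multiplier`` times the query size (capped by availability).
    Returns positional indices into ``all_tested``.
    """
    rng = np.random.default_rng(seed)
    dm_index = np.asarray(dm_index, dtype=np.int64)
    cov = all_tested["coverage"].to_numpy(dtype=float)
    n = cov.size
    if dm_index.size == 0:
        raise ValueError("empty query set")
    qs = np.quantile(cov, np.linspace(0, 1, n_strata + 1))
    qs[0], qs[-1] = -np.inf, np.inf
    stratum = np.clip(np.searchsorted(qs, cov, side="right") - 1, 0, n_strata - 1)
    is_dm = np.zeros(n, dtype=bool)
    is_dm[dm_index] = True
    chosen = []
    for s in range(n_strata):
        n_query = int((is_dm & (stratum == s)).sum())
        if n_query == 0:
            continue
        pool = np.flatnonzero(~is_dm & (stratum == s))
        want = min(multiplier * n_query, pool.size)
        if want:
            chosen.append(rng.choice(pool, size=want, replace=False))
    if not chosen:
        raise ValueError("no background sites available")
    return np.sort(np.concatenate(chosen))


def feature_enrichment(
    query_index, background_index, assignments: pd.DataFrame
) -> list[EnrichmentResult]:
    """Per-feature 2x2 enrichment of query vs background sites.

    One result per primary label plus an orthogonal ``enhancer_overlap``
    test; BH q across the whole family.
    """
    q_idx = np.asarray(query_index, dtype=np.int64)
    b_idx = np.asarray(background_index, dtype=np.int64)
    if q_idx.size == 0 or b_idx.size == 0:
        raise ValueError("query and background must be non-empty")
    labels = assignments["primary_label"].to_numpy()
    enh = assignments["enhancer_overlap"].to_numpy(dtype=bool)
    results = []
    for feature in FEATURE_LABELS:
        in_q = labels[q_idx] == feature
        in_b = labels[b_idx] == feature
        results.append(
            EnrichmentResult(
                label=feature,
                a=int(in_q.sum()),
                b=int(q_idx.size - in_q.sum()),
                c=int(in_b.sum()),
                d=int(b_idx.size - in_b.sum()),
            )
        )
    results.append(
        EnrichmentResult(
            label="enhancer_overlap",
            a=int(enh[q_idx].sum()),
            b=int(q_idx.size - enh[q_idx].sum()),
            c=int(enh[b_idx].sum()),
            d=int(b_idx.size - enh[b_idx].sum()),
        )
    )
    return finalize_q(results)


def enhancer_proximity(
    dm_sites: pd.DataFrame,
    enhancers: pd.DataFrame,
    max_dist: int = 1000,
    gene_models: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relate DM sites to the nearest enhancer: overlap / proximal / distal.

    Distance 0 means overlap; 0 < d <= max_dist proximal; otherwise distal
    (distance inf when the chromosome has no enhancer). The associated gene
    is the gene whose TSS is nearest to the enhancer-facing position.
    """
    chroms = dm_sites["chrom"].to_numpy()
    pos = dm_sites["pos"].to_numpy(dtype=np.int64)
    n = pos.size
    dist = np.full(n, np.inf)
    enh_row = np.full(n, -1, dtype=np.int64)
    enh = enhancers.reset_index(drop=True)
    for chrom, sub in enh.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        p = pos[mask]
        # distance from point to [s, e): 0 inside, gap to the closer edge outside
        d = np.maximum.reduce([s[None, :] - p[:, None], p[:, None] - (e[None, :] - 1),
                               np.zeros((p.size, s.size), dtype=np.int64)])
        best = np.argmin(d, axis=1)
        dist[mask] = d[np.arange(p.size), best]
        enh_row[mask] = sub.index.to_numpy()[best]
    relation = np.where(dist == 0, "overlap", np.where(dist <= max_dist, "proximal", "distal"))

    # associated gene: the gene whose TSS is nearest to the nearest enhancer
    gene = np.full(n, None, dtype=object)
    if gene_models is not None and len(gene_models):
        tss = gene_tss(gene_models)
        assoc_cache: dict[int, object] = {}
        for i in range(n):
            r = int(enh_row[i])
            if r < 0:
                continue
            if r not in assoc_cache:
                row = enh.iloc[r]
                sub = tss[tss["chrom"] == row["chrom"]].sort_values("gene_id", kind="stable")
                if not len(sub):
                    assoc_cache[r] = None
                else:
                    t = sub["tss"].to_numpy()
                    d = np.maximum.reduce([
                        row["start"] - t, t - (row["end"] - 1), np.zeros(t.size, dtype=np.int64)
                    ])
                    assoc_cache[r] = sub["gene_id"].to_numpy()[int(np.argmin(d))]
            gene[i] = assoc_cache[r]

    out = dm_sites[["chrom", "pos"]].copy().reset_index(drop=True)
    out["relation"] = relation
    out["enhancer_distance"] = dist
    out["associated_gene"] = gene
    return out
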
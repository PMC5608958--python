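"""Ortholog-mapped gene-set enrichment, methylation-expression correlation,
and relative-expression (copy-number fraction) summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import EnrichmentResult, spearman_with_p

__all__ = [
    "map_orthologs",
    "fisher_set_enrichment",
    "GeneSetEnrichment",
    "meth_expr_correlation",
    "cell_type_fraction",
]


def map_orthologs(human_set, ortholog_table: pd.DataFrame):
    """Map human symbols to mouse ids through a two-column table.

    Many-to-many rows expand to all mouse targets (set semantics); symbols
    absent from the table are reported unmapped. Returns
    (mouse id set, sorted unmapped symbol list).
    """
    if not len(ortholog_table):
        raise ValueError("empty ortholog table")
    cols = list(ortholog_table.columns[:2])
    lookup: dict[str, set[str]] = {}
    for h, m in ortholog_table[cols].itertuples(index=False):
        lookup.setdefault(str(h), set()).add(str(m))
    mapped: set[str] = set()
    unmapped: list[str] = []
    for symbol in set(human_set):
        targets = lookup.get(symbol)
        if targets:
            mapped |= targets
        else:
            unmapped.append(symbol)
    return mapped, sorted(unmapped)


@dataclass
class GeneSetEnrichment:
    set_name: str
    n_set_mapped: int
    n_set_de: int
    universe: int
    result: EnrichmentResult


def fisher_set_enrichment(set_ids, de_ids, universe_ids, set_name: str = "set"):
    """Fisher over-representation of a gene set among DE genes.

    a = |set & de|, b = |set \\ de|, c = |de \\ set|, d = rest of the universe.
    The set and DE ids must both be subsets of the universe.
    """
    universe = set(universe_ids)
    sset = set(set_ids)
    de = set(de_ids)
    if not sset:
        raise ValueError("empty gene set")
    offenders = sorted(sset - universe)
    if offenders:
        raise ValueError(f"set ids outside the universe: {offenders[:10]}")
    offenders = sorted(de - universe)
    if offenders:
        raise ValueError(f"DE ids outside the universe: {offenders[:10]}")
    a = len(sset & de)
    b = len(sset - de)
    c = len(de - sset)
    d = len(universe) - a - b - c
    return GeneSetEnrichment(
        set_name=set_name,
        n_set_mapped=len(sset),
        n_set_de=a,
        universe=len(universe),
        result=EnrichmentResult(label=set_name, a=a, b=b, c=c, d=d),
    )


def meth_expr_correlation(
    dm_sites: pd.DataFrame,
    assignments: pd.DataFrame,
    de_table: pd.DataFrame,
    max_tss_dist: int = 500_000,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Per-feature-class Spearman correlation of site delta vs nearest-gene log2FC.

    Sites pair with their assigned nearest gene when |TSS distance| <=
    ``max_tss_dist``. Classes with fewer than ``min_pairs`` pairs (or
    undefined rho) report NA.
    """
    merged = dm_sites.merge(assignments, on=["chrom", "pos"], how="inner")
    lfc = de_table.set_index("id")["log2fc"]
    rows = []
    for klass, sub in merged.groupby("primary_label"):
        sub = sub[np.abs(sub["tss_distance"]) <= max_tss_dist]
        sub = sub[sub["nearest_gene"].notna()]
        pairs = [
            (d, lfc[g])
            for d, g in zip(sub["delta_pp"], sub["nearest_gene"])
            if g in lfc.index
        ]
        if len(pairs) < min_pairs:
            rho, p = np.nan, np.nan
        else:
            x, y = zip(*pairs)
            rho, p = spearman_with_p(x, y)
        rows.append(
            {"feature_class": klass, "n_pairs": len(pairs), "spearman_rho": rho, "p": p}
        )
    return pd.DataFrame(rows, columns=["feature_class", "n_pairs", "spearman_rho", "p"])


def cell_type_fraction(copy_numbers: pd.DataFrame) -> pd.DataFrame:
    """Per-gene percentages of summed copy-number values across cell types.

    Rows are genes, columns cell types; each output row sums to 100. Negative
    values or an all-zero gene are errors.
    """
    values = copy_numbers.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("copy numbers must be non-negative")
    totals = values.sum(axis=1)
    zero = totals == 0
    if zero.any():
        bad = list(copy_numbers.index[zero])
        raise ValueError(f"all-zero copy numbers for: {bad}")
    return pd.DataFrame(
        100.0 * values / totals[:, None],
        index=copy_numbers.index,
        columns=copy_numbers.columns,
    )
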
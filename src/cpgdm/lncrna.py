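"""High-confidence antisense/intergenic lncRNA classification.

Rules, applied in order: reject transcripts with spliced length <= min_len
(strictly greater than min_len required), with a positive coding-potential
flag, or with any exonic same-strand overlap of a coding gene. Survivors are
antisense when their exons overlap a coding gene on the opposite strand and
intergenic otherwise; high confidence requires a same-strand CAGE cluster
within ``cage_max_dist`` of the transcript 5' end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import gene_tss

__all__ = ["classify_lncrnas", "pair_with_neighbor_genes"]


def _five_prime(row) -> int:
    return int(row["start"] if row["strand"] == "+" else row["end"] - 1)


def _exon_gene_overlap(exons: pd.DataFrame, genes: pd.DataFrame, strand_mode: str) -> bool:
    """Any overlap between the transcript's exons and a coding gene body."""
    for _, ex in exons.iterrows():
        sub = genes[genes["chrom"] == ex["chrom"]]
        if strand_mode == "same":
            sub = sub[sub["strand"] == ex["strand"]]
        elif strand_mode == "opposite":
            sub = sub[sub["strand"] != ex["strand"]]
        if ((sub["start"] < ex["end"]) & (sub["end"] > ex["start"])).any():
            return True
    return False


def classify_lncrnas(
    candidates: pd.DataFrame,
    candidate_exons: pd.DataFrame,
    coding_flags: pd.DataFrame,
    coding_genes: pd.DataFrame,
    cage_clusters: pd.DataFrame,
    min_len: int = 200,
    cage_max_dist: int = 50,
    require_cage: bool = False,
) -> pd.DataFrame:
    """Classify candidate transcripts as antisense / intergenic / rejected.

    ``candidates``: transcript_id, chrom, start, end, strand.
    ``candidate_exons``: per-exon intervals keyed by transcript_id.
    ``coding_flags``: transcript_id, coding_potential (bool input; prediction
    itself is out of scope).
    With ``require_cage=True`` transcripts lacking CAGE support are rejected
    (reason no_cage_support) instead of merely losing the high-confidence flag.
    """
    flags = dict(zip(coding_flags["transcript_id"], coding_flags["coding_potential"]))
    exons_by_tx = dict(tuple(candidate_exons.groupby("transcript_id")))
    rows = []
    for _, tx in candidates.iterrows():
        tid = tx["transcript_id"]
        exons = exons_by_tx.get(tid)
        if exons is None or not len(exons):
            raise ValueError(f"transcript {tid} has no exons")
        spliced_len = int((exons["end"] - exons["start"]).sum())

        klass, reason = None, None
        if spliced_len <= min_len:
            klass, reason = "rejected", "too_short"
        elif bool(flags.get(tid, False)):
            klass, reason = "rejected", "coding_potential"
        elif _exon_gene_overlap(exons, coding_genes, "same"):
            klass, reason = "rejected", "sense_overlap"

        # CAGE support at the 5' end, same strand, within cage_max_dist
        p5 = _five_prime(tx)
        cage = cage_clusters[
            (cage_clusters["chrom"] == tx["chrom"])
            & (cage_clusters["strand"] == tx["strand"])
        ]
        if len(cage):
            s = cage["start"].to_numpy()
            e = cage["end"].to_numpy()
            d = np.maximum.reduce([s - p5, p5 - (e - 1), np.zeros(s.size, dtype=np.int64)])
            has_cage = bool((d <= cage_max_dist).any())
        else:
            has_cage = False

        if klass is None and require_cage and not has_cage:
            klass, reason = "rejected", "no_cage_support"
        if klass is None:
            if _exon_gene_overlap(exons, coding_genes, "opposite"):
                klass = "antisense"
            else:
                klass = "intergenic"
        rows.append(
            {
                "transcript_id": tid,
                "klass": klass,
                "reject_reason": reason,
                "high_confidence": bool(klass != "rejected" and has_cage),
                "spliced_length": spliced_len,
                "chrom": tx["chrom"],
                "start": int(tx["start"]),
                "end": int(tx["end"]),
                "strand": tx["strand"],
            }
        )
    return pd.DataFrame(rows)


def pair_with_neighbor_genes(
    lncrna_calls: pd.DataFrame,
    gene_models: pd.DataFrame,
    de_table: pd.DataFrame,
    max_dist: int = 100_000,
) -> pd.DataFrame:
    """Pair each accepted lncRNA with its nearest coding-gene TSS within max_dist.

    Concordant means both partners are DE with the same log2FC sign. Ties in
    TSS distance go to the lexicographically lower gene id.
    """
    de = de_table.set_index("id")
    tss = gene_tss(gene_models).sort_values("gene_id", kind="stable")
    rows = []
    for _, lnc in lncrna_calls.iterrows():
        if lnc["klass"] == "rejected":
            continue
        p5 = _five_prime(lnc)
        sub = tss[tss["chrom"] == lnc["chrom"]]
        gene_id, dist = None, np.inf
        if len(sub):
            d = np.abs(sub["tss"].to_numpy() - p5)
            best = int(np.argmin(d))
            if d[best] <= max_dist:
                gene_id, dist = sub["gene_id"].to_numpy()[best], int(d[best])

        def de_info(ident):
            if ident is not None and ident in de.index:
                row = de.loc[ident]
                return float(row["log2fc"]), float(row["padj"]), bool(row["is_de"])
            return np.nan, np.nan, False

        l_fc, l_p, l_de = de_info(lnc["transcript_id"])
        g_fc, g_p, g_de = de_info(gene_id)
        concordant = bool(
            gene_id is not None and l_de and g_de and np.sign(l_fc) == np.sign(g_fc)
        )
        rows.append(
            {
                "lncrna": lnc["transcript_id"],
                "lncrna_log2fc": l_fc,
                "lncrna_padj": l_p,
                "nearest_gene": gene_id if gene_id is not None else "none",
                "gene_log2fc": g_fc,
                "gene_padj": g_p,
                "distance": dist,
                "concordant": concordant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lncrna", "lncrna_log2fc", "lncrna_padj", "nearest_gene",
                 "gene_log2fc", "gene_padj", "distance", "concordant"],
    )
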
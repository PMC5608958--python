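"""Lightweight genomic-interval utilities (0-based, half-open throughout)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["merge_intervals", "GenomicIntervals", "gene_tss", "nearest_tss"]


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge possibly-overlapping intervals into a sorted disjoint union."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class GenomicIntervals:
    """Per-chromosome merged interval index supporting membership and distance.

    Built from a DataFrame with at least chrom/start/end columns; intervals
    may overlap (they are merged internally for the union queries).
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom"):
            self._merged[chrom] = merge_intervals(
                sub["start"].to_numpy(), sub["end"].to_numpy()
            )

    def contains(self, chroms, positions) -> np.ndarray:
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(positions.size, dtype=bool)
        for chrom, (s, e) in self._merged.items():
            mask = chroms == chrom
            if not mask.any() or s.size == 0:
                continue
            pos = positions[mask]
            idx = np.searchsorted(s, pos, side="right") - 1
            ok = idx >= 0
            hit = np.zeros(pos.size, dtype=bool)
            hit[ok] = pos[ok] < e[idx[ok]]
            out[mask] = hit
        return out

    def nearest_distance(self, chroms, positions) -> np.ndarray:
        """Distance from each point to the closest interval (0 if inside).

        Chromosomes with no intervals get ``inf``.
        """
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.size, np.inf)
        for chrom, (s, e) in self._merged.items():
            mask = chroms == chrom
            if not mask.any() or s.size == 0:
                continue
            pos = positions[mask]
            idx = np.searchsorted(s, pos, side="right") - 1
            d = np.full(pos.size, np.inf)
            ok = idx >= 0
            # gap to the interval on/left of the point; 0 when inside
            d[ok] = np.maximum(pos[ok] - (e[idx[ok]] - 1), 0)
            nxt = idx + 1
            has_next = nxt < s.size
            d_right = np.full(pos.size, np.inf)
            d_right[has_next] = s[nxt[has_next]] - pos[has_next]
            out[mask] = np.minimum(d, d_right)
        return out


def gene_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene TSS positions (0-based): start on '+', end-1 on '-'."""
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "tss": tss.astype(np.int64),
            "strand": genes["strand"].to_numpy(),
        }
    )


def nearest_tss(chroms, positions, tss_df: pd.DataFrame):
    """Nearest gene TSS per point, ties broken by lexicographically lower id.

    Returns (gene_id object array with None for chromosomes lacking genes,
    signed distance float array: negative = upstream of the gene's TSS with
    respect to the gene's strand).
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    gene_ids = np.full(positions.size, None, dtype=object)
    signed = np.full(positions.size, np.nan)
    for chrom, sub in tss_df.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        sub = sub.sort_values("gene_id", kind="stable")
        tss = sub["tss"].to_numpy()
        strands = sub["strand"].to_numpy()
        ids = sub["gene_id"].to_numpy()
        pos = positions[mask]
        dist = np.abs(pos[:, None] - tss[None, :])
        # argmin returns the first minimum => lowest gene id wins ties
        best = np.argmin(dist, axis=1)
        d = pos - tss[best]
        flip = strands[best] == "-"
        d[flip] = -d[flip]
        gene_ids[mask] = ids[best]
        signed[mask] = d
    return gene_ids, signed
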
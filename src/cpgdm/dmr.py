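"""DMR chaining and TAD-level DM summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["cluster_dmrs", "tad_dm_fraction"]


def cluster_dmrs(
    dm_sites: pd.DataFrame, max_gap: int = 500, min_sites: int = 2
) -> pd.DataFrame:
    """Chain DM CpGs into regions by single linkage on sorted positions.

    Consecutive sites at most ``max_gap`` bp apart (boundary inclusive) join
    the same chain; chains with >= ``min_sites`` members become regions. The
    region span covers member dyads only: end = last member position + 2.
    Direction is hyper/hypo when all member deltas share a sign, else mixed.

    ``dm_sites`` needs chrom, pos and delta_pp columns; order is irrelevant.
    """
    if max_gap < 0 or min_sites < 1:
        raise ValueError("max_gap must be >=0 and min_sites >=1")
    rows = []
    if len(dm_sites):
        for chrom, sub in dm_sites.groupby("chrom", sort=True):
            sub = sub.sort_values("pos", kind="stable")
            pos = sub["pos"].to_numpy(dtype=np.int64)
            delta = sub["delta_pp"].to_numpy(dtype=float)
            breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
            for chunk_pos, chunk_delta in zip(
                np.split(pos, breaks), np.split(delta, breaks)
            ):
                if chunk_pos.size < min_sites:
                    continue
                if (chunk_delta > 0).all():
                    direction = "hyper"
                elif (chunk_delta < 0).all():
                    direction = "hypo"
                else:
                    direction = "mixed"
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(chunk_pos[0]),
                        "end": int(chunk_pos[-1]) + 2,
                        "n_sites": int(chunk_pos.size),
                        "mean_delta_pp": float(chunk_delta.mean()),
                        "direction": direction,
                        "member_positions": [int(p) for p in chunk_pos],
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_sites", "mean_delta_pp",
            "direction", "member_positions",
        ],
    )


def tad_dm_fraction(
    all_sites: pd.DataFrame,
    dm_sites: pd.DataFrame,
    tads: pd.DataFrame,
    gene_annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-TAD tested/DM CpG counts, percent DM, and contained genes.

    percent_dm is NaN (reported as NA) for TADs with no tested CpGs, 0 for
    TADs with tested sites but no DM sites. TADs must be non-overlapping per
    chromosome.
    """
    for chrom, sub in tads.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping TADs on {chrom}")

    def count_in(tad, sites):
        if not len(sites):
            return 0
        sub = sites[sites["chrom"] == tad["chrom"]]
        return int(((sub["pos"] >= tad["start"]) & (sub["pos"] < tad["end"])).sum())

    rows = []
    for _, tad in tads.iterrows():
        n_tested = count_in(tad, all_sites)
        n_dm = count_in(tad, dm_sites)
        pct = 100.0 * n_dm / n_tested if n_tested > 0 else np.nan
        genes = ""
        if gene_annotations is not None and len(gene_annotations):
            g = gene_annotations
            hit = (
                (g["chrom"] == tad["chrom"])
                & (g["start"] < tad["end"])
                & (g["end"] > tad["start"])
            )
            genes = ",".join(sorted(g.loc[hit, "gene_id"]))
        rows.append(
            {
                "name": tad.get("name", ""),
                "chrom": tad["chrom"],
                "start": int(tad["start"]),
                "end": int(tad["end"]),
                "n_tested": n_tested,
                "n_dm": n_dm,
                "percent_dm": pct,
                "genes": genes,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["name", "chrom", "start", "end", "n_tested", "n_dm", "percent_dm", "genes"],
    )
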
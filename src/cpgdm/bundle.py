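"""Annotation bundle: gene models, interval tracks, and genome sequence.

All coordinates are 0-based half-open. The genome is held as mutable per-chrom
numpy character arrays so the simulator can plant motif instances in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_TRACK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def empty_track() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "name": pd.Series(dtype=str),
            "score": pd.Series(dtype=float),
            "strand": pd.Series(dtype=str),
        }
    )


@dataclass
class AnnotationBundle:
    """Gene/transcript models plus enhancer/CpG-island/TAD/CAGE tracks."""

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, gene_type
    exons: pd.DataFrame  # gene_id, transcript_id, chrom, start, end, strand
    enhancers: pd.DataFrame = field(default_factory=empty_track)
    cpg_islands: pd.DataFrame = field(default_factory=empty_track)
    tads: pd.DataFrame = field(default_factory=empty_track)
    cage_clusters: pd.DataFrame = field(default_factory=empty_track)
    genome: dict[str, np.ndarray] | None = None  # chrom -> dtype '<U1' array

    def sequence(self, chrom: str) -> str:
        if self.genome is None:
            raise ValueError("bundle carries no genome sequence")
        return "".join(self.genome[chrom])

    def coding_genes(self) -> pd.DataFrame:
        if "gene_type" not in self.genes.columns:
            return self.genes
        return self.genes[self.genes["gene_type"] == "protein_coding"]

    def validate(self) -> None:
        for df, label in [(self.genes, "genes"), (self.exons, "exons")]:
            bad = set(df["chrom"]) - set(self.chrom_sizes)
            if bad:
                raise ValueError(f"{label} reference unknown chromosomes: {sorted(bad)}")
        if (self.genes["end"] <= self.genes["start"]).any():
            raise ValueError("gene interval with end <= start")

    def cpg_positions(self) -> dict[str, np.ndarray]:
        """Positions of the C of every CG dinucleotide, per chromosome."""
        if self.genome is None:
            raise ValueError("bundle carries no genome sequence")
        out = {}
        for chrom, seq in self.genome.items():
            if seq.size < 2:
                out[chrom] = np.empty(0, dtype=np.int64)
                continue
            mask = (seq[:-1] == "C") & (seq[1:] == "G")
            out[chrom] = np.flatnonzero(mask).astype(np.int64)
        return out
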
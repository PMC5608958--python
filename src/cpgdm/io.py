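"""Readers and writers for the standard formats the pipeline speaks.

Coordinate conventions: BED is 0-based half-open, GTF is 1-based closed, and
Bismark-coverage files are 1-based; everything is converted to the internal
0-based half-open representation on read and back on write.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .bundle import AnnotationBundle
from .methylome import MethylomeTable
from .motifs import PWM, SequenceWindow

__all__ = [
    "write_fasta", "read_fasta",
    "write_gtf", "read_gtf",
    "write_bed", "read_bed",
    "write_bismark_coverage", "read_methylome_table",
    "write_de_table", "read_de_table",
    "read_gene_set", "write_gene_set", "read_gmt",
    "read_ortholog_map", "write_ortholog_map",
    "read_meme_minimal", "write_meme_minimal", "read_pwm_tsv",
    "write_windows_fasta",
    "read_annotation_inputs", "write_annotation_bundle",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


# --- FASTA -----------------------------------------------------------------


def write_fasta(genome: dict[str, np.ndarray], path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = "".join(genome[chrom])
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = np.array(list(str(rec.seq).upper()), dtype="<U1")
    return genome


# --- GTF -------------------------------------------------------------------


def write_gtf(genes: pd.DataFrame, exons: pd.DataFrame, path) -> None:
    """Genes + exons as GTF (1-based, closed intervals)."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            attrs = f'gene_id "{g["gene_id"]}"; gene_type "{g.get("gene_type", "protein_coding")}";'
            fh.write(
                f"{g['chrom']}\tcpgdm\tgene\t{g['start'] + 1}\t{g['end']}\t.\t"
                f"{g['strand']}\t.\t{attrs}\n"
            )
        for _, e in exons.iterrows():
            attrs = (
                f'gene_id "{e["gene_id"]}"; transcript_id "{e["transcript_id"]}"; '
                f'exon_number "{e.get("exon_number", 1)}";'
            )
            fh.write(
                f"{e['chrom']}\tcpgdm\texon\t{e['start'] + 1}\t{e['end']}\t.\t"
                f"{e['strand']}\t.\t{attrs}\n"
            )


_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (genes, exons) with 0-based half-open coordinates."""
    gene_rows, exon_rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start, end, _, strand, _, attr_text = fields
            attrs = dict(_ATTR_RE.findall(attr_text))
            start0, end0 = int(start) - 1, int(end)
            if feature == "gene":
                gene_rows.append(
                    (attrs.get("gene_id", ""), chrom, start0, end0, strand,
                     attrs.get("gene_type", "protein_coding"))
                )
            elif feature == "exon":
                exon_rows.append(
                    (attrs.get("gene_id", ""), attrs.get("transcript_id", ""),
                     chrom, start0, end0, strand, int(attrs.get("exon_number", 1)))
                )
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"]
    )
    exons = pd.DataFrame(
        exon_rows,
        columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand", "exon_number"],
    )
    if not len(genes) and len(exon_rows):
        # transcript-only GTF (e.g. lncRNA candidates): synthesise transcript spans
        spans = exons.groupby("transcript_id").agg(
            chrom=("chrom", "first"), start=("start", "min"),
            end=("end", "max"), strand=("strand", "first"),
        ).reset_index()
        genes = spans.rename(columns={"transcript_id": "gene_id"})
        genes["gene_type"] = "unknown"
    return genes, exons


# --- BED -------------------------------------------------------------------


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    out = df.copy()
    for col, default in [("name", "."), ("score", 0.0), ("strand", ".")]:
        if col not in out.columns:
            out[col] = default
    cols = _BED_COLS + (extra_cols or [])
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_BED_COLS)
    df = df.iloc[:, :6]
    df.columns = _BED_COLS[: df.shape[1]]
    for col, default in [("name", "."), ("score", 0.0), ("strand", ".")]:
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


# --- Bismark coverage ------------------------------------------------------


def write_bismark_coverage(table: MethylomeTable, directory, prefix: str = "") -> dict[str, Path]:
    """One 6-column coverage file per sample (1-based positions, raw counts).

    Absent counts (NaN) are skipped, not written as zero.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    pos1 = table.sites["pos"].to_numpy(dtype=np.int64) + 1
    chroms = table.sites["chrom"].to_numpy()
    for j, sample in enumerate(table.samples):
        m = table.meth[:, j]
        u = table.unmeth[:, j]
        present = ~(np.isnan(m) | np.isnan(u))
        cov = m[present] + u[present]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * m[present] / cov, 0.0)
        df = pd.DataFrame(
            {
                "chrom": chroms[present],
                "start": pos1[present],
                "end": pos1[present],
                "pct": np.round(pct, 6),
                "meth": m[present].astype(np.int64),
                "unmeth": u[present].astype(np.int64),
            }
        )
        path = directory / f"{prefix}{sample}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths[sample] = path
    return paths


def read_methylome_table(
    sample_paths: dict[str, str | Path],
    conditions: dict[str, str],
    genome: dict[str, np.ndarray] | None = None,
) -> MethylomeTable:
    """Union of per-sample Bismark coverage files; missing counts are absent.

    The methylation-% column is ignored in favour of the raw counts. With a
    genome, strand is assigned from the reference base (C -> '+', G -> '-');
    without one, records are treated as already-collapsed ('+').
    """
    samples = list(sample_paths)
    frames = {}
    for sample in samples:
        path = sample_paths[sample]
        try:
            df = pd.read_csv(
                path, sep="\t", header=None,
                names=["chrom", "pos1", "end1", "pct", "meth", "unmeth"],
                dtype={"chrom": str},
            )
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["chrom", "pos1", "end1", "pct", "meth", "unmeth"])
        for col in ("meth", "unmeth"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
            if bad.any():
                lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise ValueError(f"{path}:{lineno}: non-integer or negative {col} count")
            df[col] = vals.astype(np.int64)
        df["pos"] = df["pos1"].astype(np.int64) - 1
        frames[sample] = df.set_index(["chrom", "pos"])[["meth", "unmeth"]]

    all_index = None
    for df in frames.values():
        idx = df.index
        all_index = idx if all_index is None else all_index.union(idx)
    if all_index is None or not len(all_index):
        sites = pd.DataFrame({"chrom": [], "pos": [], "strand": []})
        empty = np.empty((0, len(samples)))
        return MethylomeTable(sites, empty.copy(), empty.copy(), samples, dict(conditions))
    all_index = all_index.sortlevel()[0]

    n = len(all_index)
    meth = np.full((n, len(samples)), np.nan)
    unmeth = np.full((n, len(samples)), np.nan)
    for j, sample in enumerate(samples):
        aligned = frames[sample].reindex(all_index)
        meth[:, j] = aligned["meth"].to_numpy()
        unmeth[:, j] = aligned["unmeth"].to_numpy()

    chroms = all_index.get_level_values(0).to_numpy()
    positions = all_index.get_level_values(1).to_numpy(dtype=np.int64)
    if genome is not None:
        strand = np.full(n, "+", dtype=object)
        for chrom in np.unique(chroms):
            seq = genome.get(chrom)
            if seq is None:
                continue
            mask = chroms == chrom
            pos_c = np.clip(positions[mask], 0, seq.size - 1)
            strand[mask] = np.where(seq[pos_c] == "G", "-", "+")
    else:
        strand = np.full(n, "+", dtype=object)
    sites = pd.DataFrame({"chrom": chroms, "pos": positions, "strand": strand})
    return MethylomeTable(sites, meth, unmeth, samples, dict(conditions))


# --- tables ----------------------------------------------------------------


def write_de_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if "is_de" not in df.columns:
        df["is_de"] = df["padj"] < 0.05
    df["is_de"] = df["is_de"].astype(bool)
    return df


def read_gene_set(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_set(symbols, path) -> None:
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sets[fields[0]] = [f for f in fields[2:] if f]
    return sets


def read_ortholog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map needs two columns")
    return df.iloc[:, :2].drop_duplicates().reset_index(drop=True)


def write_ortholog_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# --- PWMs ------------------------------------------------------------------


def read_meme_minimal(path) -> list[PWM]:
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.column_stack([m.pwm[b] for b in "ACGT"])
        bg = np.array([m.background[b] for b in "ACGT"])
        out.append(PWM(name=m.name, matrix=mat, background=bg / bg.sum()))
    return out


def write_meme_minimal(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 1000000 E= 0\n"  # large nsites: keep probability resolution
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_pwm_tsv(path, name: str | None = None) -> PWM:
    """Simple matrix dialect: header A C G T, one probability row per position."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in ["A", "C", "G", "T"] if c in df.columns]
    if len(cols) != 4:
        raise ValueError("PWM TSV needs A/C/G/T columns")
    return PWM(name=name or Path(path).stem, matrix=df[["A", "C", "G", "T"]].to_numpy())


def write_windows_fasta(windows: list[SequenceWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.site_id}\n{w.sequence}\n")


# --- annotation bundle round trip ------------------------------------------


def write_annotation_bundle(bundle: AnnotationBundle, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "genome.fa",
        "gtf": directory / "genes.gtf",
        "enhancers": directory / "enhancers.bed",
        "cpg_islands": directory / "cpg_islands.bed",
        "tads": directory / "tads.bed",
        "cage": directory / "cage_clusters.bed",
    }
    if bundle.genome is not None:
        write_fasta(bundle.genome, paths["fasta"])
    write_gtf(bundle.genes, bundle.exons, paths["gtf"])
    write_bed(bundle.enhancers, paths["enhancers"])
    write_bed(bundle.cpg_islands, paths["cpg_islands"])
    write_bed(bundle.tads, paths["tads"])
    write_bed(bundle.cage_clusters, paths["cage"])
    if getattr(bundle, "lncrna_candidates", None) is not None:
        paths["lncrna_gtf"] = directory / "lncrna_candidates.gtf"
        write_gtf(
            bundle.lncrna_candidates.rename(columns={"transcript_id": "gene_id"}).assign(
                gene_type="candidate"
            ),
            bundle.lncrna_exons,
            paths["lncrna_gtf"],
        )
        paths["coding_flags"] = directory / "coding_flags.tsv"
        bundle.lncrna_coding_flags.to_csv(paths["coding_flags"], sep="\t", index=False)
    return paths


def read_annotation_inputs(
    gtf_path,
    fasta_path=None,
    enhancers_bed=None,
    cpg_islands_bed=None,
    tads_bed=None,
    cage_bed=None,
) -> AnnotationBundle:
    """Assemble a validated bundle from on-disk annotation files."""
    genes, exons = read_gtf(gtf_path)
    genome = read_fasta(fasta_path) if fasta_path else None
    if genome is not None:
        chrom_sizes = {c: int(genome[c].size) for c in genome}
        missing = set(genes["chrom"]) - set(chrom_sizes)
        if missing:
            raise ValueError(f"FASTA missing GTF chromosomes: {sorted(missing)}")
    else:
        chrom_sizes = {
            c: int(sub["end"].max()) + 1 for c, sub in genes.groupby("chrom")
        }
    from .bundle import empty_track

    def load(path):
        return read_bed(path) if path else empty_track()

    bundle = AnnotationBundle(
        chrom_sizes=chrom_sizes,
        genes=genes,
        exons=exons,
        enhancers=load(enhancers_bed),
        cpg_islands=load(cpg_islands_bed),
        tads=load(tads_bed),
        cage_clusters=load(cage_bed),
        genome=genome,
    )
    bundle.validate()
    return bundle
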
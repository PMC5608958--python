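"""Hand-built 10-transcript candidate annotation covering every classifier
branch, with hand-derived expected labels."""

import pandas as pd

CHROM_LEN = 200_000

# coding genes: GA (+) and GB (-)
CODING_GENES = pd.DataFrame(
    {
        "gene_id": ["GA", "GB"],
        "chrom": ["chrT", "chrT"],
        "start": [10_000, 50_000],
        "end": [20_000, 60_000],
        "strand": ["+", "-"],
        "gene_type": ["protein_coding", "protein_coding"],
    }
)

# transcript_id, chrom, start, end, strand
_CANDIDATES = [
    ("T01", "chrT", 100_000, 100_150, "+"),   # 150 nt -> too_short
    ("T02", "chrT", 105_000, 105_200, "+"),   # exactly 200 nt -> too_short (strict >)
    ("T03", "chrT", 120_000, 120_201, "+"),   # 201 nt, CAGE at 5' -> intergenic, high conf
    ("T04", "chrT", 130_000, 130_800, "+"),   # coding-potential flag -> rejected
    ("T05", "chrT", 11_000, 11_800, "+"),     # same-strand overlap of GA -> sense_overlap
    ("T06", "chrT", 12_000, 12_800, "-"),     # opposite strand over GA, CAGE -> antisense HC
    ("T07", "chrT", 14_000, 14_800, "-"),     # opposite strand over GA, no CAGE -> antisense
    ("T08", "chrT", 150_000, 150_800, "-"),   # far from genes, no CAGE -> intergenic
    ("T09", "chrT", 48_000, 52_000, "+"),     # 2nd exon overlaps GB (-) -> antisense
    ("T10", "chrT", 58_000, 62_000, "-"),     # exon overlaps GB same strand -> sense_overlap
]

CANDIDATES = pd.DataFrame(
    _CANDIDATES, columns=["transcript_id", "chrom", "start", "end", "strand"]
)

_EXONS = [
    ("T01", 100_000, 100_150),
    ("T02", 105_000, 105_200),
    ("T03", 120_000, 120_201),
    ("T04", 130_000, 130_800),
    ("T05", 11_000, 11_800),
    ("T06", 12_000, 12_800),
    ("T07", 14_000, 14_800),
    ("T08", 150_000, 150_800),
    ("T09", 48_000, 48_300),   # outside any gene
    ("T09", 51_500, 52_000),   # inside GB
    ("T10", 58_000, 58_300),   # inside GB, same strand
    ("T10", 61_500, 62_000),
]


def _exon_frame():
    strands = dict(zip(CANDIDATES["transcript_id"], CANDIDATES["strand"]))
    rows = []
    counters: dict[str, int] = {}
    for tid, s, e in _EXONS:
        counters[tid] = counters.get(tid, 0) + 1
        rows.append((tid, tid, "chrT", s, e, strands[tid], counters[tid]))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand", "exon_number"],
    )


CANDIDATE_EXONS = _exon_frame()

CODING_FLAGS = pd.DataFrame(
    {
        "transcript_id": [t[0] for t in _CANDIDATES],
        "coding_potential": [tid == "T04" for tid, *_ in _CANDIDATES],
    }
)

# CAGE: supports T03 (+, near 120,000) and T06 (-, near its 5' end 12,799)
CAGE = pd.DataFrame(
    {
        "chrom": ["chrT", "chrT"],
        "start": [119_990, 12_790],
        "end": [120_010, 12_810],
        "name": ["cage1", "cage2"],
        "score": [0.0, 0.0],
        "strand": ["+", "-"],
    }
)

EXPECTED = {
    "T01": ("rejected", "too_short", False),
    "T02": ("rejected", "too_short", False),
    "T03": ("intergenic", None, True),
    "T04": ("rejected", "coding_potential", False),
    "T05": ("rejected", "sense_overlap", False),
    "T06": ("antisense", None, True),
    "T07": ("antisense", None, False),
    "T08": ("intergenic", None, False),
    "T09": ("antisense", None, False),
    "T10": ("rejected", "sense_overlap", False),
}


def mirrored():
    """Coordinate-mirrored, strand-flipped copy of the toy annotation."""

    def flip(df):
        out = df.copy()
        start = CHROM_LEN - out["end"]
        end = CHROM_LEN - out["start"]
        out["start"], out["end"] = start, end
        out["strand"] = out["strand"].map({"+": "-", "-": "+"})
        return out

    return flip(CANDIDATES), flip(CANDIDATE_EXONS), flip(CODING_GENES), flip(CAGE)
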
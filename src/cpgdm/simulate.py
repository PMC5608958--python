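"""Ground-truth simulator for every input the analysis consumes.

Emits an annotation bundle with a random genome, beta-binomial bisulfite
counts with planted differentially methylated regions, motif instances
written into the sequence near planted DM CpGs, and differential-expression
tables with a planted enriched gene set — together with a ``TruthSet``
recording exactly what was planted, so recovery can be tested end to end.

All randomness flows from a single integer seed: the three ``simulate_*``
entry points derive independent streams from ``(seed, stage)`` seed
sequences, so each output is a pure function of its config.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import AnnotationBundle
from .intervals import merge_intervals

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "PlantedDMR",
    "SimulationError",
    "simulate_annotation_bundle",
    "simulate_methylome_experiment",
    "simulate_expression_tables",
]

_BASES = np.array(["A", "C", "G", "T"])

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class SimulationError(ValueError):
    """Raised when a requested simulation is infeasible."""


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome / annotation
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    gc_fraction: float = 0.42
    n_genes: int = 30
    exons_per_gene: tuple[int, int] = (2, 5)
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    n_enhancers: int = 30
    n_cpg_islands: int = 15
    n_tads: int = 8
    n_cage_clusters: int = 40
    n_lncrna_candidates: int = 12
    # methylome
    n_replicates_per_condition: int = 3
    mean_depth: float = 30.0
    depth_dispersion: float = 8.0  # negative-binomial size; larger = closer to Poisson
    baseline_meth_mixture: tuple[tuple[float, float], tuple[float, float], float] = (
        (1.2, 6.0),
        (6.0, 1.2),
        0.45,
    )  # (hypo Beta), (hyper Beta), weight of hypo component
    replicate_dispersion: float = 300.0  # beta-binomial precision; -> binomial as it grows
    n_planted_dmrs: int = 0
    dmr_n_cpgs: int = 5
    dmr_delta_pp: float = 40.0
    dmr_feature_weights: dict[str, float] = field(
        default_factory=lambda: {"intron": 1.0, "enhancer": 1.0, "other": 1.0}
    )
    # motif planting
    motif_consensus: str = "TGACTCA"
    motif_planting_fraction: float = 0.0
    motif_background_fraction: float = 0.0
    # expression
    n_expressed_genes: int | None = None  # None -> bundle genes only
    n_de_genes: int = 8
    de_log2fc: float = 2.0
    emt_set_size: int = 10
    emt_de_odds_ratio: float = 3.0
    ortholog_unmapped_fraction: float = 0.0

    def validate(self) -> None:
        for name in ("gc_fraction", "motif_planting_fraction",
                     "motif_background_fraction", "ortholog_unmapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1], got {v}")
        if not -100.0 < self.dmr_delta_pp < 100.0:
            raise SimulationError("dmr_delta_pp must lie in (-100, 100)")
        if self.n_chromosomes < 1 or self.chrom_length < 100:
            raise SimulationError("need at least one chromosome of >=100 bp")
        if self.n_replicates_per_condition < 1:
            raise SimulationError("need >=1 replicate per condition")
        if self.dmr_n_cpgs < 1:
            raise SimulationError("dmr_n_cpgs must be positive")
        n_expr = self.n_expressed_genes or self.n_genes
        if self.emt_set_size > n_expr:
            raise SimulationError("emt_set_size exceeds the expressed-gene universe")
        (a1, b1), (a2, b2), w = self.baseline_meth_mixture
        if min(a1, b1, a2, b2) <= 0 or not 0 <= w <= 1:
            raise SimulationError("invalid baseline methylation mixture")


@dataclass
class PlantedDMR:
    chrom: str
    start: int
    end: int
    delta_pp: float
    cpg_positions: list[int]


@dataclass
class TruthSet:
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    planted_de_ids: list[tuple[str, float, bool]] = field(default_factory=list)
    planted_motif_sites: list[tuple[str, int, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_dmrs": [dataclasses.asdict(d) for d in self.planted_dmrs],
                "planted_de_ids": [list(t) for t in self.planted_de_ids],
                "planted_motif_sites": [list(t) for t in self.planted_motif_sites],
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        obj = json.loads(text)
        return cls(
            planted_dmrs=[PlantedDMR(**d) for d in obj.get("planted_dmrs", [])],
            planted_de_ids=[tuple(t) for t in obj.get("planted_de_ids", [])],
            planted_motif_sites=[tuple(t) for t in obj.get("planted_motif_sites", [])],
        )


# ---------------------------------------------------------------------------
# annotation bundle
# ---------------------------------------------------------------------------


def _partition_counts(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def _segment_lengths(rng, total: int, k: int, min_len: int) -> np.ndarray:
    """k segment lengths >= min_len summing exactly to total."""
    extra = total - k * min_len
    if extra < 0:
        raise SimulationError("segments do not fit")
    parts = rng.multinomial(extra, np.full(k, 1.0 / k))
    return parts + min_len


def simulate_annotation_bundle(config: SimulationConfig) -> AnnotationBundle:
    """Random genome + non-overlapping multi-exon gene models + interval tracks."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    gc = config.gc_fraction
    p_bases = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    genome = {
        chrom: _BASES[rng.choice(4, size=size, p=p_bases)]
        for chrom, size in chrom_sizes.items()
    }

    genes_rows, exons_rows = [], []
    min_gap = 200
    per_chrom = _partition_counts(config.n_genes, config.n_chromosomes)
    gidx = 0
    lo, hi = config.gene_length_range
    for chrom, n_here in zip(chrom_sizes, per_chrom):
        if n_here == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n_here)
        free = config.chrom_length - int(lengths.sum()) - (n_here + 1) * min_gap
        if free < 0:
            raise SimulationError(
                f"cannot place {n_here} genes of total length {lengths.sum()} "
                f"on {chrom} ({config.chrom_length} bp)"
            )
        gap_extra = rng.multinomial(free, np.full(n_here + 1, 1.0 / (n_here + 1)))
        pos = 0
        for i in range(n_here):
            pos += min_gap + int(gap_extra[i])
            start, end = pos, pos + int(lengths[i])
            pos = end
            strand = str(rng.choice(["+", "-"]))
            gene_id = f"G{gidx:04d}"
            gidx += 1
            genes_rows.append((gene_id, chrom, start, end, strand, "protein_coding"))
            k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            segs = _segment_lengths(rng, end - start, 2 * k - 1, 60)
            cursor = start
            exon_no = 0
            for j, seg in enumerate(segs):
                if j % 2 == 0:
                    exon_no += 1
                    exons_rows.append(
                        (gene_id, f"{gene_id}.1", chrom, cursor, cursor + int(seg), strand, exon_no)
                    )
                cursor += int(seg)

    genes = pd.DataFrame(
        genes_rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"]
    )
    exons = pd.DataFrame(
        exons_rows,
        columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand", "exon_number"],
    )

    def random_track(n, len_lo, len_hi, prefix, stranded=False):
        rows = []
        chroms = list(chrom_sizes)
        for i in range(n):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(len_lo, len_hi + 1))
            start = int(rng.integers(0, max(1, chrom_sizes[chrom] - length)))
            strand = str(rng.choice(["+", "-"])) if stranded else "."
            rows.append((chrom, start, start + length, f"{prefix}{i:04d}", 0.0, strand))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        )

    enhancers = random_track(config.n_enhancers, 300, 1500, "ENH")
    cpg_islands = random_track(config.n_cpg_islands, 200, 1000, "CGI")

    tad_rows = []
    per_chrom_tads = _partition_counts(config.n_tads, config.n_chromosomes)
    t = 0
    for chrom, k in zip(chrom_sizes, per_chrom_tads):
        if k == 0:
            continue
        min_tad = min(2000, max(1, chrom_sizes[chrom] // (2 * k)))
        segs = _segment_lengths(rng, chrom_sizes[chrom], k, min_tad)
        cursor = 0
        for seg in segs:
            tad_rows.append((chrom, cursor, cursor + int(seg), f"TAD{t:03d}", 0.0, "."))
            cursor += int(seg)
            t += 1
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    bundle = AnnotationBundle(
        chrom_sizes=chrom_sizes,
        genes=genes,
        exons=exons,
        enhancers=enhancers,
        cpg_islands=cpg_islands,
        tads=tads,
        genome=genome,
    )
    _add_lncrna_candidates(bundle, config, rng)
    _add_cage_clusters(bundle, config, rng)
    bundle.validate()
    return bundle


def _add_lncrna_candidates(bundle, config, rng) -> None:
    """Plant non-coding transcript candidates covering every classifier branch."""
    rows, exon_rows, flags = [], [], []
    genes = bundle.genes
    chroms = list(bundle.chrom_sizes)
    kinds = ["antisense", "intergenic", "short", "coding", "sense"]
    for i in range(config.n_lncrna_candidates):
        tid = f"LNC{i:03d}"
        kind = kinds[i % len(kinds)]
        coding_flag = kind == "coding"
        if kind in ("antisense", "coding", "sense") and len(genes):
            g = genes.iloc[int(rng.integers(len(genes)))]
            strand = g["strand"] if kind == "sense" else ("-" if g["strand"] == "+" else "+")
            length = int(rng.integers(400, 1200))
            start = int(max(0, g["start"] + rng.integers(0, max(1, g["end"] - g["start"] - length))))
            chrom = g["chrom"]
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            strand = str(rng.choice(["+", "-"]))
            length = 150 if kind == "short" else int(rng.integers(400, 1200))
            # drop into a gene-free gap when possible
            start = _intergenic_start(bundle, rng, chrom, length)
        end = start + length
        rows.append((tid, chrom, start, end, strand))
        exon_rows.append((tid, tid, chrom, start, end, strand, 1))
        flags.append((tid, coding_flag))
    bundle.lncrna_candidates = pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "start", "end", "strand"]
    )
    bundle.lncrna_exons = pd.DataFrame(
        exon_rows,
        columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand", "exon_number"],
    )
    bundle.lncrna_coding_flags = pd.DataFrame(flags, columns=["transcript_id", "coding_potential"])


def _intergenic_start(bundle, rng, chrom, length) -> int:
    size = bundle.chrom_sizes[chrom]
    sub = bundle.genes[bundle.genes["chrom"] == chrom]
    occupied_s, occupied_e = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    gaps = []
    prev = 0
    for s, e in zip(occupied_s, occupied_e):
        if s - prev >= length + 200:
            gaps.append((prev + 100, s - length - 100))
        prev = max(prev, e)
    if size - prev >= length + 200:
        gaps.append((prev + 100, size - length - 100))
    if not gaps:
        return int(rng.integers(0, max(1, size - length)))
    lo, hi = gaps[int(rng.integers(len(gaps)))]
    return int(rng.integers(lo, hi + 1))


def _add_cage_clusters(bundle, config, rng) -> None:
    rows = []
    tss_sources = []
    for _, g in bundle.genes.iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"] - 1
        tss_sources.append((g["chrom"], int(tss), g["strand"]))
    for _, t in bundle.lncrna_candidates.iterrows():
        tss = t["start"] if t["strand"] == "+" else t["end"] - 1
        tss_sources.append((t["chrom"], int(tss), t["strand"]))
    chroms = list(bundle.chrom_sizes)
    for i in range(config.n_cage_clusters):
        if tss_sources and rng.random() < 0.7:
            chrom, tss, strand = tss_sources[int(rng.integers(len(tss_sources)))]
            width = int(rng.integers(5, 25))
            start = max(0, tss - width // 2)
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            width = int(rng.integers(5, 25))
            start = int(rng.integers(0, max(1, bundle.chrom_sizes[chrom] - width)))
            strand = str(rng.choice(["+", "-"]))
        rows.append((chrom, start, start + width, f"CAGE{i:04d}", 0.0, strand))
    bundle.cage_clusters = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


# ---------------------------------------------------------------------------
# methylome experiment
# ---------------------------------------------------------------------------


def _intron_intervals(bundle) -> pd.DataFrame:
    rows = []
    exons_by_gene = dict(tuple(bundle.exons.groupby("gene_id")))
    for _, g in bundle.genes.iterrows():
        ex = exons_by_gene.get(g["gene_id"])
        if ex is None:
            continue
        s, e = merge_intervals(ex["start"].to_numpy(), ex["end"].to_numpy())
        prev = g["start"]
        for xs, xe in zip(s, e):
            if xs > prev:
                rows.append((g["chrom"], prev, xs))
            prev = xe
        if g["end"] > prev:
            rows.append((g["chrom"], prev, g["end"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _cpg_categories(bundle, cpgs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Label each CpG intron/enhancer/other for weighted DMR placement.

    Uses the same precedence as downstream feature assignment so planted
    'intron' sites are recovered as intronic by the analysis.
    """
    import pandas as pd

    from .annotation import assign_features

    out = {}
    for chrom, pos in cpgs.items():
        if pos.size == 0:
            out[chrom] = np.empty(0, dtype=object)
            continue
        sites = pd.DataFrame({"chrom": chrom, "pos": pos})
        assigned = assign_features(sites, bundle)
        label = assigned["primary_label"].to_numpy()
        enh = assigned["enhancer_overlap"].to_numpy(dtype=bool)
        cat = np.full(pos.size, "other", dtype=object)
        cat[enh & np.isin(label, ["enhancer", "intergenic", "cpg_island"])] = "enhancer"
        cat[label == "intron"] = "intron"
        out[chrom] = cat
    return out


def _choose_dmr_runs(rng, config, cpgs, categories):
    """Pick disjoint runs of consecutive CpGs, weighted by anchor category."""
    anchors = []  # (chrom, index into cpg array)
    weights = []
    wmap = config.dmr_feature_weights
    k = config.dmr_n_cpgs
    for chrom, pos in cpgs.items():
        if pos.size < k:
            continue
        gaps_ok = np.ones(pos.size - k + 1, dtype=bool)
        if k > 1:
            # every internal gap of the run must stay comfortably below the
            # DMR chaining cutoff so planted regions are recoverable
            gap = np.diff(pos)
            run_gap_ok = gap <= 400
            for off in range(k - 1):
                gaps_ok &= run_gap_ok[off : off + gaps_ok.size]
        cat = categories[chrom]
        for i in np.flatnonzero(gaps_ok):
            run_cats = set(cat[i : i + k].tolist())
            if len(run_cats) != 1:
                continue  # members must share a category so planting is clean
            anchors.append((chrom, int(i)))
            weights.append(float(wmap.get(run_cats.pop(), wmap.get("other", 1.0))))
    if not anchors:
        raise SimulationError(
            f"no run of {k} CpGs with gaps <=400 bp exists on any chromosome"
        )
    weights = np.asarray(weights)
    weights = weights / weights.sum()
    chosen: list[tuple[str, int]] = []
    used: dict[str, list[tuple[int, int]]] = {}
    order = rng.choice(len(anchors), size=len(anchors), replace=False, p=weights)
    for idx in order:
        chrom, i = anchors[idx]
        pos = cpgs[chrom]
        lo, hi = int(pos[i]), int(pos[i + config.dmr_n_cpgs - 1]) + 2
        # keep planted regions well separated so they stay distinct DMRs
        if any(lo - 1000 < e and hi + 1000 > s for s, e in used.get(chrom, [])):
            continue
        chosen.append((chrom, i))
        used.setdefault(chrom, []).append((lo, hi))
        if len(chosen) == config.n_planted_dmrs:
            return chosen
    raise SimulationError(
        f"could only place {len(chosen)} of {config.n_planted_dmrs} requested DMRs; "
        "increase genome size or reduce dmr_n_cpgs"
    )


def _resolve_iupac(rng, consensus: str) -> str:
    out = []
    for ch in consensus.upper():
        opts = IUPAC.get(ch)
        if opts is None:
            raise SimulationError(f"invalid IUPAC symbol {ch!r} in motif consensus")
        out.append(opts[int(rng.integers(len(opts)))])
    return "".join(out)


def _plant_motifs(rng, bundle, config, member_positions, cpgs, truth) -> None:
    """Write motif instances into the genome near chosen CpGs.

    Planted segments never overlap a protected CpG dyad (the planted DMR
    members and the background anchor itself), so those sites survive.
    """
    L = len(config.motif_consensus)
    protected: dict[str, set[int]] = {}
    for chrom, positions in member_positions.items():
        s = protected.setdefault(chrom, set())
        for p in positions:
            s.add(p)
            s.add(p + 1)

    planted: dict[str, list[tuple[int, int]]] = {}

    def plant_near(chrom: str, p: int) -> None:
        size = bundle.chrom_sizes[chrom]
        half = 20
        starts = [
            s0
            for s0 in range(max(0, p - half + 3), min(size - L, p + half - L - 2) + 1)
            if not any(q in protected.get(chrom, ()) for q in range(s0, s0 + L))
            and not (s0 <= p + 1 and p < s0 + L)
            and not any(s0 < e and s0 + L > s for s, e in planted.get(chrom, []))
        ]
        if not starts:
            return
        s0 = starts[int(rng.integers(len(starts)))]
        seq = _resolve_iupac(rng, config.motif_consensus)
        bundle.genome[chrom][s0 : s0 + L] = list(seq)
        planted.setdefault(chrom, []).append((s0, s0 + L))
        truth.planted_motif_sites.append((chrom, s0, "+"))

    # DM-proximal plantings
    for chrom in sorted(member_positions):
        for p in member_positions[chrom]:
            if rng.random() < config.motif_planting_fraction:
                protected.setdefault(chrom, set()).update((p, p + 1))
                plant_near(chrom, p)
    # background plantings near non-member CpGs
    if config.motif_background_fraction > 0:
        for chrom in sorted(cpgs):
            members = set(member_positions.get(chrom, []))
            bg = [int(p) for p in cpgs[chrom] if int(p) not in members]
            n_bg = rng.binomial(len(bg), config.motif_background_fraction)
            for p in rng.choice(len(bg), size=min(n_bg, len(bg)), replace=False):
                pos = bg[int(p)]
                protected.setdefault(chrom, set()).update((pos, pos + 1))
                plant_near(chrom, pos)


def simulate_methylome_experiment(bundle: AnnotationBundle, config: SimulationConfig):
    """Beta-binomial per-strand bisulfite counts with planted DMRs.

    Returns ``(MethylomeTable, TruthSet)``. Mutates ``bundle.genome`` in place
    when motif planting is enabled (write the FASTA afterwards).
    """
    from .methylome import MethylomeTable

    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    truth = TruthSet()
    cpgs = bundle.cpg_positions()

    member_positions: dict[str, list[int]] = {}
    if config.n_planted_dmrs > 0:
        categories = _cpg_categories(bundle, cpgs)
        runs = _choose_dmr_runs(rng, config, cpgs, categories)
        for chrom, i in runs:
            positions = [int(p) for p in cpgs[chrom][i : i + config.dmr_n_cpgs]]
            member_positions.setdefault(chrom, []).extend(positions)
            truth.planted_dmrs.append(
                PlantedDMR(
                    chrom=chrom,
                    start=positions[0],
                    end=positions[-1] + 2,
                    delta_pp=config.dmr_delta_pp,
                    cpg_positions=positions,
                )
            )

    if config.motif_planting_fraction > 0 or config.motif_background_fraction > 0:
        _plant_motifs(rng, bundle, config, member_positions, cpgs, truth)
        cpgs = bundle.cpg_positions()  # motif writes may create/destroy CpGs

    n_rep = config.n_replicates_per_condition
    samples = [f"uncut_{i + 1}" for i in range(n_rep)] + [
        f"cut_{i + 1}" for i in range(n_rep)
    ]
    conditions = {s: ("uncut" if s.startswith("uncut") else "cut") for s in samples}

    (a1, b1), (a2, b2), w_hypo = config.baseline_meth_mixture
    delta = config.dmr_delta_pp / 100.0
    phi = config.replicate_dispersion
    size_nb = config.depth_dispersion
    mu_strand = config.mean_depth / 2.0
    p_nb = size_nb / (size_nb + mu_strand)

    site_rows = []
    meth_cols: list[np.ndarray] = []
    unmeth_cols: list[np.ndarray] = []
    for chrom in sorted(cpgs):
        pos = cpgs[chrom]
        n = pos.size
        if n == 0:
            continue
        hypo = rng.random(n) < w_hypo
        base = np.where(hypo, rng.beta(a1, b1, size=n), rng.beta(a2, b2, size=n))
        members = np.asarray(sorted(set(member_positions.get(chrom, []))), dtype=np.int64)
        if members.size:
            is_member = np.isin(pos, members)
            # draw planted baselines with full headroom for the shift
            lo = 0.05 + max(0.0, -delta)
            hi = 0.95 - max(0.0, delta)
            base[is_member] = rng.uniform(lo, hi, size=int(is_member.sum()))
        else:
            is_member = np.zeros(n, dtype=bool)
        mu_uncut = np.clip(base, 1e-4, 1 - 1e-4)
        mu_cut = np.where(is_member, np.clip(base + delta, 0.0, 1.0), base)
        mu_cut = np.clip(mu_cut, 1e-4, 1 - 1e-4)

        chrom_meth = {s: None for s in samples}
        chrom_unmeth = {s: None for s in samples}
        for s in samples:
            mu = mu_cut if conditions[s] == "cut" else mu_uncut
            p_rep = rng.beta(mu * phi, (1 - mu) * phi)
            cov_p = rng.negative_binomial(size_nb, p_nb, size=n)
            cov_m = rng.negative_binomial(size_nb, p_nb, size=n)
            meth_p = rng.binomial(cov_p, p_rep)
            meth_m = rng.binomial(cov_m, p_rep)
            chrom_meth[s] = (meth_p, meth_m)
            chrom_unmeth[s] = (cov_p - meth_p, cov_m - meth_m)

        # interleave + and - strand records: (pos, '+'), (pos+1, '-')
        n2 = 2 * n
        rows_pos = np.empty(n2, dtype=np.int64)
        rows_pos[0::2] = pos
        rows_pos[1::2] = pos + 1
        rows_strand = np.empty(n2, dtype=object)
        rows_strand[0::2] = "+"
        rows_strand[1::2] = "-"
        site_rows.append(
            pd.DataFrame({"chrom": chrom, "pos": rows_pos, "strand": rows_strand})
        )
        meth_block = np.empty((n2, len(samples)))
        unmeth_block = np.empty((n2, len(samples)))
        for j, s in enumerate(samples):
            meth_block[0::2, j] = chrom_meth[s][0]
            meth_block[1::2, j] = chrom_meth[s][1]
            unmeth_block[0::2, j] = chrom_unmeth[s][0]
            unmeth_block[1::2, j] = chrom_unmeth[s][1]
        meth_cols.append(meth_block)
        unmeth_cols.append(unmeth_block)

    if site_rows:
        sites = pd.concat(site_rows, ignore_index=True)
        meth = np.vstack(meth_cols)
        unmeth = np.vstack(unmeth_cols)
    else:
        sites = pd.DataFrame({"chrom": [], "pos": [], "strand": []})
        meth = np.empty((0, len(samples)))
        unmeth = np.empty((0, len(samples)))
    sites["one_sided"] = False

    table = MethylomeTable(
        sites=sites, meth=meth, unmeth=unmeth, samples=samples, conditions=conditions
    )
    return table, truth


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def _solve_enrichment_probs(n_set, n_other, n_de, odds_ratio):
    """Per-gene DE probabilities (in-set, out-of-set) hitting the target
    expected DE count with the requested in-set odds ratio."""
    from scipy.optimize import brentq

    total = n_set + n_other
    if not 0 < n_de < total:
        raise SimulationError("requested DE count infeasible for the universe")
    if odds_ratio <= 0:
        raise SimulationError("odds ratio must be positive")

    def expected_minus_target(p_out):
        odds_in = odds_ratio * p_out / (1 - p_out)
        p_in = odds_in / (1 + odds_in)
        return n_set * p_in + n_other * p_out - n_de

    lo, hi = 1e-12, 1 - 1e-12
    if expected_minus_target(lo) > 0 or expected_minus_target(hi) < 0:
        raise SimulationError(
            f"enrichment OR={odds_ratio} infeasible for margins "
            f"(set={n_set}, universe={total}, de={n_de})"
        )
    p_out = brentq(expected_minus_target, lo, hi, xtol=1e-12)
    odds_in = odds_ratio * p_out / (1 - p_out)
    return odds_in / (1 + odds_in), p_out


def simulate_expression_tables(bundle: AnnotationBundle, config: SimulationConfig):
    """DE table + EMT gene set + ortholog map with a planted enrichment.

    Returns ``(de_table, gene_sets, ortholog_map, TruthSet)`` where
    ``gene_sets`` maps set name to a list of human symbols and the ortholog
    map is a two-column human->mouse DataFrame.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    ids = list(bundle.genes["gene_id"])
    n_expr = config.n_expressed_genes or len(ids)
    if n_expr < len(ids):
        ids = ids[:n_expr]
    ids += [f"X{i:05d}" for i in range(len(ids), n_expr)]
    n = len(ids)

    emt_idx = rng.choice(n, size=config.emt_set_size, replace=False)
    in_emt = np.zeros(n, dtype=bool)
    in_emt[emt_idx] = True

    p_in, p_out = _solve_enrichment_probs(
        config.emt_set_size, n - config.emt_set_size, config.n_de_genes,
        config.emt_de_odds_ratio,
    )
    de = rng.random(n) < np.where(in_emt, p_in, p_out)

    log2fc = rng.normal(0.0, 0.25, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    log2fc[de] = signs[de] * (config.de_log2fc + np.abs(rng.normal(0.0, 0.3, size=int(de.sum()))))
    padj = np.where(de, 10 ** (-rng.uniform(2, 8, size=n)), rng.uniform(0.051, 1.0, size=n))

    de_table = pd.DataFrame(
        {"id": ids, "log2fc": log2fc, "padj": padj, "is_de": de}
    )

    id_arr = np.asarray(ids, dtype=object)
    emt_mouse = sorted(id_arr[in_emt])
    human = [f"EMTH{i:04d}" for i in range(len(emt_mouse))]
    n_unmapped = int(round(config.ortholog_unmapped_fraction * len(human)))
    unmapped = set(
        rng.choice(len(human), size=n_unmapped, replace=False).tolist()
    )
    ortholog_map = pd.DataFrame(
        [(h, m) for i, (h, m) in enumerate(zip(human, emt_mouse)) if i not in unmapped],
        columns=["human_symbol", "mouse_id"],
    )
    gene_sets = {"EMT": human}

    truth = TruthSet(
        planted_de_ids=[
            (ids[i], float(log2fc[i]), bool(in_emt[i])) for i in np.flatnonzero(de)
        ]
    )
    return de_table, gene_sets, ortholog_map, truth
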
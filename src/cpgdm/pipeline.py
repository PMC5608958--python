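"""End-to-end orchestration: config, stage sequencing, and report outputs.

``run_pipeline`` executes collapse/filter -> per-site testing -> BH -> DM
calling -> DMR chaining -> feature assignment/enrichment -> TSS bins -> TAD
table -> motif enrichment -> lncRNA classification -> gene sets ->
methylation-expression correlation, writing plain-text outputs plus a run
log. Outputs are a pure function of (config, seed): no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, annotation, dmr, genesets, io, lncrna, methylome, motifs

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("dm", "dmr", "annotate", "enrich", "motif", "lncrna", "genesets")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    # inputs
    sample_paths: dict[str, str] = field(default_factory=dict)
    sample_conditions: dict[str, str] = field(default_factory=dict)
    fasta: str | None = None
    gtf: str | None = None
    enhancers_bed: str | None = None
    cpg_islands_bed: str | None = None
    tads_bed: str | None = None
    cage_bed: str | None = None
    de_table: str | None = None
    gene_set: str | None = None
    gene_set_name: str = "EMT"
    ortholog_map: str | None = None
    pwms_meme: str | None = None
    lncrna_gtf: str | None = None
    coding_flags: str | None = None
    # thresholds
    min_cov: int = 5
    coverage_scope: str = "every-sample"
    dm_method: str = "pooled-fisher"
    q_threshold: float = 0.05
    delta_threshold: float = 20.0
    max_gap: int = 500
    min_sites: int = 2
    window_width: int = 40
    min_len: int = 200
    cage_max_dist: int = 50
    promoter_upstream: int = -1500
    promoter_downstream: int = 500
    score_fraction: float = 0.8
    coverage_matched_background: bool = True
    background_multiplier: int = 10
    background_strata: int = 10
    max_tss_dist: int = 500_000
    # run
    seed: int = 0
    outdir: str = "cpgdm_out"

    def validate(self) -> None:
        if not 0 < self.q_threshold <= 1:
            raise ValueError(f"q_threshold {self.q_threshold} outside (0, 1]")
        if not 0 <= self.delta_threshold < 100:
            raise ValueError("delta_threshold outside [0, 100)")
        if self.min_cov < 0 or self.max_gap < 0 or self.min_sites < 1:
            raise ValueError("invalid DMR/coverage thresholds")
        if self.window_width <= 0 or self.window_width % 2:
            raise ValueError("window_width must be positive and even")
        if not 0 < self.score_fraction <= 1:
            raise ValueError("score_fraction outside (0, 1]")
        if self.coverage_scope not in ("every-sample", "pooled"):
            raise ValueError(f"unknown coverage scope {self.coverage_scope!r}")
        for sample in self.sample_paths:
            if sample not in self.sample_conditions:
                raise ValueError(f"sample {sample!r} has no condition label")
        for label, path in self.input_paths().items():
            if path and not Path(path).exists():
                raise FileNotFoundError(f"{label} input does not exist: {path}")

    def input_paths(self) -> dict[str, str | None]:
        out = {f"sample:{s}": p for s, p in self.sample_paths.items()}
        out.update(
            fasta=self.fasta, gtf=self.gtf, enhancers=self.enhancers_bed,
            cpg_islands=self.cpg_islands_bed, tads=self.tads_bed,
            cage=self.cage_bed, de_table=self.de_table, gene_set=self.gene_set,
            ortholog_map=self.ortholog_map, pwms=self.pwms_meme,
            lncrna_gtf=self.lncrna_gtf, coding_flags=self.coding_flags,
        )
        return out

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        cfg = cls()
        inputs = doc.get("inputs", {})
        key_map = {
            "fasta": "fasta", "gtf": "gtf", "enhancers": "enhancers_bed",
            "cpg_islands": "cpg_islands_bed", "tads": "tads_bed",
            "cage": "cage_bed", "de_table": "de_table", "gene_set": "gene_set",
            "gene_set_name": "gene_set_name", "ortholog_map": "ortholog_map",
            "pwms": "pwms_meme", "lncrna_gtf": "lncrna_gtf",
            "coding_flags": "coding_flags",
        }
        for key, attr in key_map.items():
            if key in inputs:
                setattr(cfg, attr, inputs[key])
        for entry in doc.get("samples", []):
            cfg.sample_paths[entry["name"]] = entry["path"]
            cfg.sample_conditions[entry["name"]] = entry["condition"]
        for key, value in doc.get("thresholds", {}).items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown threshold {key!r}")
            setattr(cfg, key, value)
        run = doc.get("run", {})
        cfg.seed = int(run.get("seed", cfg.seed))
        cfg.outdir = run.get("outdir", cfg.outdir)
        return cfg

    def to_toml(self, path) -> None:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            return json.dumps(str(v))

        lines = ["[inputs]"]
        key_map = [
            ("fasta", self.fasta), ("gtf", self.gtf),
            ("enhancers", self.enhancers_bed), ("cpg_islands", self.cpg_islands_bed),
            ("tads", self.tads_bed), ("cage", self.cage_bed),
            ("de_table", self.de_table), ("gene_set", self.gene_set),
            ("gene_set_name", self.gene_set_name),
            ("ortholog_map", self.ortholog_map), ("pwms", self.pwms_meme),
            ("lncrna_gtf", self.lncrna_gtf), ("coding_flags", self.coding_flags),
        ]
        for key, value in key_map:
            if value:
                lines.append(f"{key} = {fmt(value)}")
        for sample, p in self.sample_paths.items():
            lines.append("\n[[samples]]")
            lines.append(f"name = {fmt(sample)}")
            lines.append(f"path = {fmt(p)}")
            lines.append(f"condition = {fmt(self.sample_conditions[sample])}")
        lines.append("\n[thresholds]")
        for key in (
            "min_cov", "coverage_scope", "dm_method", "q_threshold",
            "delta_threshold", "max_gap", "min_sites", "window_width", "min_len",
            "cage_max_dist", "promoter_upstream", "promoter_downstream",
            "score_fraction", "coverage_matched_background",
            "background_multiplier", "background_strata", "max_tss_dist",
        ):
            lines.append(f"{key} = {fmt(getattr(self, key))}")
        lines.append("\n[run]")
        lines.append(f"seed = {self.seed}")
        lines.append(f"outdir = {fmt(self.outdir)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _write_dm_bed(dm: pd.DataFrame, path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": dm["chrom"],
            "start": dm["pos"],
            "end": dm["pos"] + 2,
            "name": dm["q"].map(lambda v: f"{v:.6g}"),
            "score": dm["delta_pp"].abs().round(3),
            "strand": ".",
        }
    )
    io.write_bed(bed, path)


def _enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label, "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "odds_ratio": r.odds_ratio, "ci_low": r.ci_low,
                "ci_high": r.ci_high, "p": r.p, "q": r.q,
            }
            for r in results
        ]
    )


def run_pipeline(config: PipelineConfig, stages=ALL_STAGES) -> dict:
    """Run the requested stages; returns a result dict (also logged to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "cpgdm_version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "min_cov", "coverage_scope", "dm_method", "q_threshold",
                "delta_threshold", "max_gap", "min_sites", "window_width",
                "min_len", "cage_max_dist", "score_fraction",
            )
        },
        "stages": list(stages),
    }
    results: dict = {"log": log}

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    with stage("inputs"):
        bundle = io.read_annotation_inputs(
            config.gtf, config.fasta, config.enhancers_bed,
            config.cpg_islands_bed, config.tads_bed, config.cage_bed,
        )
        table = io.read_methylome_table(
            config.sample_paths, config.sample_conditions, bundle.genome
        )

    with stage("dm"):
        collapsed = methylome.collapse_and_filter(
            table, min_cov=config.min_cov, scope=config.coverage_scope
        )
        tests = methylome.test_dm(collapsed, method=config.dm_method)
        called, summary = methylome.call_dm(
            tests, q_threshold=config.q_threshold,
            delta_threshold=config.delta_threshold,
        )
        log["dm_summary"] = summary
        called.to_csv(outdir / "dm_sites.tsv", sep="\t", index=False)
        dm_sites = called[called["is_dm"]].reset_index(drop=True)
        _write_dm_bed(dm_sites, outdir / "dm_sites.bed")
        results["dm"] = called
        results["collapsed"] = collapsed

    if "dmr" in stages:
        with stage("dmr"):
            regions = dmr.cluster_dmrs(
                dm_sites, max_gap=config.max_gap, min_sites=config.min_sites
            )
            io.write_bed(
                regions.assign(
                    name=[f"DMR{i:04d}" for i in range(len(regions))],
                    score=regions["mean_delta_pp"].abs().round(3),
                    strand=".",
                ),
                outdir / "dmrs.bed",
            )
            regions.drop(columns=["member_positions"]).to_csv(
                outdir / "dmrs.tsv", sep="\t", index=False
            )
            results["dmrs"] = regions
            log["n_dmrs"] = int(len(regions))
            if len(bundle.tads):
                tad_table = dmr.tad_dm_fraction(
                    called[called["p"].notna()], dm_sites, bundle.tads, bundle.genes
                )
                tad_table.to_csv(outdir / "tad_dm.tsv", sep="\t", index=False, na_rep="NA")
                results["tads"] = tad_table

    assignments = None
    bg_index = None
    tested = called[called["p"].notna()].reset_index(drop=True)
    if "annotate" in stages or "enrich" in stages or "genesets" in stages:
        with stage("annotate"):
            assignments = annotation.assign_features(
                tested, bundle,
                promoter_window=(config.promoter_upstream, config.promoter_downstream),
            )
            assignments.to_csv(outdir / "feature_assignments.tsv", sep="\t", index=False)
            results["assignments"] = assignments
            if dm_sites.shape[0] and len(bundle.genes):
                dm_assign = assignments[tested["is_dm"].to_numpy()]
                bins = annotation.tss_distance_bins(dm_assign)
                bins.to_csv(outdir / "tss_distance_bins.tsv", sep="\t", index=False)
                results["tss_bins"] = bins

    if "enrich" in stages and assignments is not None:
        with stage("enrich"):
            dm_index = np.flatnonzero(tested["is_dm"].to_numpy())
            if dm_index.size:
                cov_table = tested.copy()
                cov_table["coverage"] = collapsed.mean_coverage()[
                    called["p"].notna().to_numpy()
                ]
                if config.coverage_matched_background:
                    bg_index = annotation.coverage_matched_background(
                        dm_index, cov_table,
                        n_strata=config.background_strata,
                        multiplier=config.background_multiplier,
                        seed=config.seed,
                    )
                else:
                    bg_index = np.setdiff1d(np.arange(len(tested)), dm_index)
                feat = annotation.feature_enrichment(dm_index, bg_index, assignments)
                _enrichment_frame(feat).to_csv(
                    outdir / "feature_enrichment.tsv", sep="\t", index=False
                )
                results["feature_enrichment"] = feat
                if len(bundle.enhancers):
                    prox = annotation.enhancer_proximity(
                        dm_sites, bundle.enhancers, gene_models=bundle.genes
                    )
                    prox.to_csv(outdir / "enhancer_proximity.tsv", sep="\t", index=False)
                    results["enhancer_proximity"] = prox
            else:
                log["enrich_note"] = "no DM sites; enrichment skipped"

    if "motif" in stages:
        with stage("motif"):
            dm_index = np.flatnonzero(tested["is_dm"].to_numpy())
            if dm_index.size and bundle.genome is not None:
                dm_windows = motifs.extract_windows(
                    tested.iloc[dm_index], bundle.genome, width=config.window_width
                )
                if bg_index is None:
                    cov_table = tested.copy()
                    cov_table["coverage"] = collapsed.mean_coverage()[
                        called["p"].notna().to_numpy()
                    ]
                    bg_index = annotation.coverage_matched_background(
                        dm_index, cov_table,
                        n_strata=config.background_strata,
                        multiplier=config.background_multiplier,
                        seed=config.seed,
                    )
                bg_windows = motifs.extract_windows(
                    tested.iloc[bg_index], bundle.genome, width=config.window_width
                )
                io.write_windows_fasta(dm_windows, outdir / "dm_windows.fa")
                if config.pwms_meme:
                    pwms = io.read_meme_minimal(config.pwms_meme)
                    pwm_results = motifs.pwm_window_enrichment(
                        dm_windows, bg_windows, pwms,
                        score_fraction=config.score_fraction,
                    )
                    _enrichment_frame(pwm_results).to_csv(
                        outdir / "pwm_enrichment.tsv", sep="\t", index=False
                    )
                    results["pwm_enrichment"] = pwm_results
                kmers = motifs.kmer_enrichment(dm_windows, bg_windows, top_n=25)
                kmers.to_csv(outdir / "kmer_enrichment.tsv", sep="\t", index=False)
                results["kmer_enrichment"] = kmers
            else:
                log["motif_note"] = "no DM sites or no genome; motif stage skipped"

    if "lncrna" in stages and config.lncrna_gtf and config.coding_flags:
        with stage("lncrna"):
            cand_genes, cand_exons = io.read_gtf(config.lncrna_gtf)
            candidates = cand_genes.rename(columns={"gene_id": "transcript_id"})[
                ["transcript_id", "chrom", "start", "end", "strand"]
            ]
            flags = pd.read_csv(config.coding_flags, sep="\t")
            calls = lncrna.classify_lncrnas(
                candidates, cand_exons, flags, bundle.coding_genes(),
                bundle.cage_clusters, min_len=config.min_len,
                cage_max_dist=config.cage_max_dist,
            )
            calls.to_csv(outdir / "lncrna_calls.tsv", sep="\t", index=False, na_rep="NA")
            results["lncrna_calls"] = calls
            if config.de_table:
                de = io.read_de_table(config.de_table)
                pairs = lncrna.pair_with_neighbor_genes(
                    calls, bundle.coding_genes(), de
                )
                pairs.to_csv(outdir / "lncrna_pairs.tsv", sep="\t", index=False, na_rep="NA")
                results["lncrna_pairs"] = pairs

    if "genesets" in stages and config.de_table:
        with stage("genesets"):
            de = io.read_de_table(config.de_table)
            if config.gene_set and config.ortholog_map:
                symbols = io.read_gene_set(config.gene_set)
                orthologs = io.read_ortholog_map(config.ortholog_map)
                mapped, unmapped = genesets.map_orthologs(symbols, orthologs)
                universe = set(de["id"])
                enr = genesets.fisher_set_enrichment(
                    mapped & universe, set(de.loc[de["is_de"], "id"]), universe,
                    set_name=config.gene_set_name,
                )
                _enrichment_frame([enr.result]).assign(
                    n_set_mapped=enr.n_set_mapped,
                    n_unmapped=len(unmapped),
                    universe=enr.universe,
                ).to_csv(outdir / "gene_set_enrichment.tsv", sep="\t", index=False)
                results["gene_set_enrichment"] = enr
            if assignments is not None and dm_sites.shape[0]:
                corr = genesets.meth_expr_correlation(
                    dm_sites, assignments, de, max_tss_dist=config.max_tss_dist
                )
                corr.to_csv(outdir / "meth_expr_correlation.tsv", sep="\t",
                            index=False, na_rep="NA")
                results["meth_expr_correlation"] = corr

    with stage("report"):
        (outdir / "run_log.json").write_text(
            json.dumps(log, indent=1, sort_keys=True, default=str) + "\n"
        )
    return results
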
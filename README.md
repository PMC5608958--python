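# cpgdm

Differential CpG methylation analysis from whole-genome bisulfite count
tables, with the downstream context analyses that typically accompany it and
a ground-truth simulator so the entire pipeline can be exercised and
validated without external data.

What it does:

- **Per-CpG differential methylation** — collapse strand-split cytosine
  records into CpG dyads, apply a per-sample coverage filter (default ≥5
  reads in every sample), test each site with a pooled two-sided Fisher
  exact test (a replicate-aware logistic likelihood-ratio test is also
  available), Benjamini–Hochberg adjust, and call DM sites at q < 0.05 and
  |Δ| > 20 percentage points.
- **DMR chaining** — single-linkage chaining of DM CpGs within 500 bp
  (boundary-inclusive), ≥2 sites per region, plus per-TAD DM summaries.
- **Feature context and enrichment** — promoter/exon/intron/enhancer/CpG-
  island/intergenic assignment with a precedence rule and an orthogonal
  enhancer-overlap flag, TSS-distance histograms, coverage-matched
  background sampling, and per-feature Fisher enrichment with Woolf
  confidence intervals.
- **Motif enrichment** — 40-bp windows centred on DM CpGs, PWM scanning on
  both strands (log2-odds, hit = fraction of max score), and canonical
  k-mer over-representation as a deterministic de-novo stand-in.
- **lncRNA classification** — antisense/intergenic calls for candidate
  transcripts (>200 nt, no coding potential, no same-strand coding
  overlap), CAGE-supported high-confidence flagging, and pairing with
  neighbouring DE genes.
- **Gene-set integration** — ortholog mapping, Fisher over-representation
  of a gene set (e.g. EMT) among DE genes, methylation–expression Spearman
  correlations by feature class, and copy-number fraction summaries.
- **Simulator** — annotation bundles (genome FASTA, GTF, BED tracks),
  beta-binomial methylomes with planted DMRs, motif instances written into
  the sequence near planted DM CpGs, and DE tables with a planted enriched
  gene set — all deterministic given a seed and accompanied by a truth JSON.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact-test and BH
oracle agreement, DMR-chaining oracle agreement, null calibration, and
planted-truth recovery (DMRs, intron enrichment, AP-1 motif, gene set) at
fixed seeds, plus byte-level pipeline determinism.

## Command line

Generate a fully simulated input set (writes FASTA/GTF/BED/coverage/DE
tables, PWMs, a truth JSON, and a ready-to-run pipeline config):

```sh
cpgdm simulate --seed 1 --outdir demo
```

Run the full pipeline (or a stage: `dm`, `dmr`, `annotate`, `enrich`,
`motif`, `lncrna`, `genesets`):

```sh
cpgdm all --config demo/pipeline_config.toml
```

Outputs are plain TSV/BED/FASTA/JSON files under the configured output
directory, including `dm_sites.tsv`, `dmrs.bed`, `feature_enrichment.tsv`,
`pwm_enrichment.tsv`, `kmer_enrichment.tsv`, `lncrna_calls.tsv`,
`gene_set_enrichment.tsv` and a `run_log.json` echoing seed and thresholds.
Identical config + seed produces byte-identical outputs.

## Layout

```
src/cpgdm/
  simulate.py    ground-truth simulator (annotation, methylome, expression)
  methylome.py   collapse/filter, per-site tests, BH, DM calls, concordance
  dmr.py         DMR chaining, TAD summaries
  annotation.py  feature assignment, TSS bins, backgrounds, enrichment
  motifs.py      PWM + k-mer window enrichment
  lncrna.py      lncRNA classification and neighbour pairing
  genesets.py    ortholog mapping, gene-set Fisher, correlations
  stats.py       Fisher exact, odds ratios/Woolf CI, BH, Spearman
  io.py          FASTA/GTF/BED/Bismark-coverage/MEME/TSV readers & writers
  pipeline.py    config + end-to-end orchestration
  cli.py         click CLI
```
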
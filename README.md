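# metadefense

Defense-feature profiling of assembled microbial metagenomes, built for
sponge/seawater-style comparative studies and benchmarked end-to-end on
synthetic metagenomes with planted ground truth.

The pipeline covers:

- **CRISPR array detection** — one seed-and-extend repeat/spacer detector run
  under multiple parameter profiles ("strict" and "lenient" by default); an
  array is retained when found by at least two profiles, or by one profile on
  a contig that carries cas genes, and must pass structural validation
  (≥ 2 spacers, repeat homogeneity, spacer dissimilarity, length ranges).
- **cas typing** — cas gene identification from domain-hit tables via an
  editable accession→cas-name config, locus grouping, type assignment from
  signature genes (cas3 → I, cas9 → II, cas10 → III; conflicts → unknown),
  and array-to-locus adjacency linking.
- **Spacer/repeat analytics** — spacer catalogues (total/distinct/singleton
  counts), cross-sample exact sharing, and spacer→target search by seeded
  local alignment (word size 7, match +1 / mismatch −1, gap open −5 /
  extend −2, E ≤ 0.1) against phage/virus/plasmid-labelled target FASTA;
  repeat matching against a user-supplied reference FASTA (E ≤ 0.01).
- **Restriction-modification systems** — REBASE-role hits filtered at
  query coverage ≥ 70%, REase+MTase completeness pairing within 4 gene
  ordinals (Specificity recorded for type I), and transitive merging of
  same-type systems within 4 genes into non-redundant clusters.
- **Abundance and community profiling** — per-contig mean coverage,
  copies-per-megabase normalization (cpm = coverage / total mapped bp × 10⁶),
  per-feature cpm aggregation, >1.5-fold enrichment calls, Bray–Curtis
  dissimilarity with complete-linkage clustering (Newick output), LCA
  taxonomy from BLAST-tabular hits, GC distributions, and the rounded
  summary-statistic arithmetic used in the report tables.
- **Synthetic data** — a deterministic simulator that plants CRISPR arrays,
  cas operons, RMS gene pairs and decoys on random contigs, simulates
  per-position Poisson (or constant) coverage, and emits a truth ledger.

## CLI

```bash
# generate synthetic samples (config: see tests for a YAML example)
metadefense simulate --config sim.yaml --outdir data/

# individual stages
metadefense crispr --contigs data/s1.contigs.fasta --out-prefix out/s1
metadefense cas --domain-hits data/s1.domain_hits.tsv --genes data/s1.genes.tsv --out-prefix out/s1
metadefense spacers --spacers out/s1.spacers.fasta --targets targets.fasta --out out/s1.hits.tsv
metadefense rms --domain-hits data/s1.domain_hits.tsv --genes data/s1.genes.tsv --out out/s1.rms.tsv
metadefense abundance --contigs data/s1.contigs.fasta --depth data/s1.depth.tsv --out out/s1.cpm.tsv

# full pipeline with combined summary, enrichment and clustering
metadefense report --manifest manifest.yaml --outdir results/
```

The manifest is a YAML file listing per-sample paths (contigs FASTA, depth
TSV, gene table, domain hits, optional alignment hits + taxonomy) plus
optional target and repeat-reference FASTA files; every threshold has its
default in `src/metadefense/data/defaults.yaml` and can be overridden with
`--config`.

## Conventions

- All file coordinates are 1-based inclusive; depth tables are
  samtools-depth style TSV.
- Contig length filtering keeps length ≥ 1000 by default (the boundary is
  configurable).
- GC excludes N from both numerator and denominator.
- Gap costs: a gap of length L costs `gap_open + L·gap_extend`.
- E-values use a Karlin–Altschul model with λ and K computed numerically
  for the ungapped match/mismatch pair; alignment *scores* are exact
  (full affine-gap Smith–Waterman once a word seed exists).
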
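# cghcnv

A tested pipeline for copy-number-variant (CNV) surveys built around
array-CGH segment calls and sequencing read depth:

- **segment_classifier** — label training calls via trio inheritance
  (identical probe boundaries in a parent) and self-self hybridisation
  false positives; forward stepwise logistic regression on transforms of
  |log2 ratio|, length and probe count; leave-one-out crossvalidation over
  a threshold grid; a published coefficient set is built in.
- **call_filters** — failed-array QC (median + 3·MAD on probe-l2r
  variance), the |l2r| ≥ 0.1 prefilter, the post-model autosomal filter
  (p ≥ 0.95, length ≥ 1 kb, ≥ 3 probes, |l2r| ≥ 0.25), chromosome-X sex
  rules and virtual-unknown-chromosome scaffold rules.
- **cnvr_analysis** — merge calls within 1,500 bp into CNV regions
  (CNVRs), frequency spectra, reference-effect flagging, genome-fraction
  summaries, and a Kolmogorov-Smirnov test of spatial uniformity against a
  length-preserving uniform placement.
- **readdepth_caller** — 1-kb sliding-window (200-bp step) depth binning
  over a repeat mask, median-scaling GC correction, a per-chromosome
  normal/half-normal mixture over CN∈{0..4} fit by bounded likelihood
  maximisation (7 free parameters with box bounds), weighted-MAP CN
  assignment, and CNVR verification against test/reference depth tracks
  (consistent / reference-effect / discordant-type statuses).
- **verification** — per-animal ≥1-bp overlap verification across
  platforms and a literature comparison table grouped by cross-study
  overlap counts.
- **annotation_enrichment** — gene-CDS overlap proportions by CNVR type,
  duplication-vs-deletion chi-square, and a Monte-Carlo enrichment test
  with an add-one two-tailed empirical p.
- **synthetic_data** — truth-known generators for everything above: planted
  CNVRs with per-animal copy numbers and trio-consistent carriers, noisy
  CGH calls (including reference-effect and self-self false positives),
  GC-biased depth tracks, and lower-sensitivity pseudo-platform call sets.

All internal coordinates are 0-based half-open; segment-call TSVs are
read as 1-based inclusive and converted at the boundary.

## CLI

The `cghcnv` entry point exposes the pipeline stages:

```bash
cghcnv --seed 7 simulate --out-dir sim/            # synthetic dataset
cghcnv classify --segments sim/segments.tsv \
       --pedigree sim/pedigree.tsv --published-model --out scored.tsv
cghcnv filter  --scored scored.tsv --pedigree sim/pedigree.tsv --out kept.tsv
cghcnv merge   --calls kept.tsv --out cnvrs.bed
cghcnv --seed 3 spatial-test --cnvrs cnvrs.bed --genome genome.tsv --out ks.json
cghcnv rd-call --depth sim/depth_REF.bedgraph --gc sim/gc_REF.bedgraph \
       --out bins.tsv --params-out params.json
cghcnv verify  --query kept.tsv --evidence other_platform.tsv --out verify.json
cghcnv compare --ours cnvrs.bed --study lit1 lit1.bed --study lit2 lit2.bed \
       --out table.tsv
cghcnv --seed 3 annotate --cnvrs cnvrs.bed --genes genes.bed \
       --genome genome.tsv --out enrich.json
```

Global flags: `--config` (YAML key-value overrides), `--seed`, `--log-level`.

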
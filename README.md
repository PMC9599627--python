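# bloomshift

Analysis pipeline for bloom metatranscriptomes, with a synthetic-community
simulator that plants known truth so every stage is testable offline:

* **simulate** — bloom communities with negative-binomial ORF expression,
  planted log2 fold changes, taxon-group abundance dynamics, reference-diverged
  subpopulations with stage-dependent mixing, planted SNVs with per-condition
  allele frequencies, and uniform sequencing error. Emits FASTA/FASTQ/SAM plus
  truth tables.
* **count / de** — ORF × sample count matrices from primary alignments; TMM
  normalization, quantile-adjusted conditional-likelihood (common/tagwise)
  dispersion estimation, an exact two-group test under the negative binomial,
  and Benjamini–Hochberg FDR. Three modes: `global`, `groupwise` (per taxon
  group with within-group library sizes, isolating physiology from abundance)
  and `taxon_proportion` (group-aggregated counts against full library sizes).
* **pidshift** — per-read percent identity (`100·(1 − NM/aligned columns)`),
  per-sample histograms, and the conserved-shift table: ORFs whose late−mid
  identity change replicates across barrels, is ≥60% identical to the
  reference, and is significantly differentially expressed.
* **snv** — pileup-based SNV calling per sample, synonymous/nonsynonymous
  classification (standard genetic code), SNV density (called sites per
  covered ORF per taxon group), and allele-frequency trajectories with
  selective-sweep flags.
* **cluster** — Markov clustering of an ORF similarity graph (shared peptide
  k-mers by default, or a supplied edge list), and cluster-average DE with the
  retention filter: >10 members, ≥1 significant member, |mean log2FC| > 2.5.
* **biomarker** — nutrient-status indices per taxon group or genus:
  `N_index = log2(NRT2/GSII)`, `Fe_index = log2((ISIP1+2+3)/thiC)`, plus
  flavodoxin:ferredoxin and ISIP2:ferritin comparison indices, and relative
  (between-sample) status calls.

All log2 fold changes are oriented depleted/replete: positive means
upregulated under nutrient limitation.

## CLI

One JSON config drives everything (schema in
`src/bloomshift/schema/config.schema.json`, worked example in
`examples/demo_config.json`):

```sh
bloomshift run --config examples/demo_config.json --out runs/demo
# or stage by stage
bloomshift simulate --config examples/demo_config.json --out runs/demo
bloomshift count    --config examples/demo_config.json --out runs/demo
bloomshift de       --config examples/demo_config.json --out runs/demo
bloomshift pidshift --config examples/demo_config.json --out runs/demo
bloomshift snv      --config examples/demo_config.json --out runs/demo
bloomshift cluster  --config examples/demo_config.json --out runs/demo
bloomshift biomarker --config examples/demo_config.json --out runs/demo
bloomshift report   --config examples/demo_config.json --out runs/demo
```

Every stage writes plain-text outputs (TSV/FASTA/FASTQ/SAM/VCF/JSON) into the
run directory and records checksums in `manifest.json`; `report.json`
aggregates DE counts per taxon and contrast, the conserved-shift tables, SNV
density, retained clusters, and biomarker indices. Exit codes: 0 success,
2 validation error, 3 stage failure. `--seed` overrides the configured seed;
`--log-level` controls verbosity.

## Library use

```python
from bloomshift.config import SimConfig, default_demo_samples
from bloomshift.simulate import generate_references, simulate_counts_matrix
from bloomshift.expression import CountMatrix, differential_expression

cfg = SimConfig(seed=1, samples=default_demo_samples(50_000))
bundle = generate_references(cfg)
matrix = CountMatrix(simulate_counts_matrix(bundle), bundle.sample_sheet,
                     bundle.annotation)
de = differential_expression(matrix, "N", mode="groupwise")
```
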
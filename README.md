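# polymirts

Discovery of polymorphic miRNA target sites (poly-miRTS) in 3'-UTR
sequences: a tested, reusable pipeline that

- predicts miRNA binding sites on reference and variant 3'-UTR alleles
  under three complementary criteria — canonical seed match with a local
  context score, seed match gated by secondary-structure accessibility and
  ranked by over-representation, and non-canonical 3'-compensatory pairing
  (one seed defect rescued by Watson–Crick pairing to miRNA nt 13–17);
- classifies each SNP-induced site difference as **created**, **disrupted**,
  **perturbed** (score change > 2 units) or **unknown** (site overlapping
  truncated/unknown variant sequence is never counted as disrupted);
- filters candidate SNPs by call quality (≥ 50), read depth (≥ 15),
  3'-UTR membership and genome mappability (window-averaged multi-mapping
  count must equal 1 over a 2×read-length window);
- computes 3'-UTR coverage qualification (> 50% of bases covered) and
  region read proportions;
- tests allele-specific expression (two-sided exact binomial, p < 0.001)
  and cross-tissue allelic proportions (two-sided Fisher exact, p < 0.05),
  and flags miRNA/target pairs with inverse expression of the targeted
  allele;
- ships seeded synthetic-data generators that plant created/disrupted
  sites, repeat structures and inverse-expression patterns with ground
  truth, for end-to-end recovery testing.

Notes on scope: the three predictors are documented surrogates for the
published algorithm family they mirror (context scoring is a three-term
simplification; accessibility uses an in-repo deterministic MFE folder —
weighted Nussinov pairing, min-loop 3 — rather than a thermodynamic
ensemble; the compensatory detector is rule-based, not a trained model).
Scores are comparable within a predictor only.

## CLI

```sh
# write a complete synthetic scenario with planted truth
polymirts simulate --out scenario/ --genes 20 --mirnas 10 \
    --created 5 --disrupted 5 --neutral 5 --seed 1

# individual stages
polymirts predict --genome g.fa --utrs utrs.bed --mirnas mirnas.fa --out sites.tsv
polymirts classify --genome g.fa --utrs utrs.bed --mirnas mirnas.fa \
    --snps snps.vcf --out polymirts.tsv
polymirts mappability --genome g.fa -L 35 -m 2 --out track.bedgraph
polymirts filter --snps snps.vcf --genome g.fa --utrs utrs.bed --out kept.vcf
polymirts ase --allelic-counts counts.tsv --out ase.tsv

# full pipeline from a config file
polymirts run-all --config scenario/config.yaml --out out/
```

The config file is a flat YAML mapping of threshold names (see
`polymirts.config.PipelineConfig`) plus input paths (`genome`,
`utr_annotation`, `mirnas`, `snps`, and optionally `known_snps`, `depth`,
`mirna_counts`, `mrna_fpkm`, `allelic_counts`). `run-all` writes
`sites.tsv`, `polymirts.tsv`, `consensus.tsv`, `snp_filter.vcf`,
`coverage.tsv`, `ase_tests.tsv`, optional `inverse_flags.tsv`, and a
`manifest.json` recording the config snapshot, input checksums and
stage-by-stage record counts.

Formats: FASTA (genome, miRNAs), BED6 or GFF3 (`three_prime_UTR` features)
for annotation, VCF v4.x for SNPs (QUAL, INFO/DP, per-sample AD),
BedGraph for depth and mappability tracks, TSV for reports.

## Layout

| module | contents |
| --- | --- |
| `polymirts.core_io` | domain types, FASTA/BED/GFF3/VCF I/O, allele construction, dedup, nucleotide variation |
| `polymirts.target_prediction` | the three site predictors + conservation check |
| `polymirts._fold` | deterministic MFE folding backend |
| `polymirts.classify` | created/disrupted/perturbed/unknown classification, Venn consensus, tallies |
| `polymirts.mappability` | multi-mapping count track, SNP window averaging, filter |
| `polymirts.variant_filters` | quality/depth/UTR filters, novel+known merge, coverage |
| `polymirts.coexpression` | FPKM, co-expression gate, exact binomial & Fisher tests, inverse-expression flags |
| `polymirts.synthetic` | seeded generators with planted ground truth |
| `polymirts.pipeline`, `polymirts.cli` | orchestration and the `polymirts` command |
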
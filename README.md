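# naivebench

Molecular benchmarks for distinguishing naive from primed human pluripotent
stem cells, implemented as a tested analysis pipeline that runs end to end on
synthetic data:

- **Transposon transcription barcoding** — locus-level TE differential
  expression (Welch t on log2 normalized counts, BH adjustment, 2-fold +
  adjusted-p gates), per-family polarization summaries, top-N composition,
  top-SD hierarchical clustering, and PCA.
- **Embryo-stage concordance** — rank-sum stage-specific feature detection in
  single-cell embryo profiles and the fraction of each stage's markers
  upregulated in naive vs primed cells.
- **TE–gene regulation** — nearest-gene assignment with distance bins
  (in gene, <2.5, 2.5–5, 5–10, 10–20 kb, random) and per-bin expression
  correlation.
- **Methylome summaries** — coverage-weighted global and regional mCpG/mCH
  levels from allc-style call tables, an imprinted-DMR erasure classifier
  (intermediate primed band [0.30, 0.70], erased < 0.30 in both naive and
  re-primed), overexpressed-TE methylation contrasts (Mann-Whitney), and
  X-linked promoter-CGI methylation distributions.
- **Allelic X status** — SNP-level allele-specific expression with a
  ≥10-reads-in-all-samples filter, biallelic/monoallelic classification, and
  X:autosome dosage ratios.
- **ChIP metaprofiles** — depth-normalized log2(ChIP/input) averaged in
  ±20 kb windows around TE 5′ ends.
- **Chimera qPCR** — standard-curve fitting, human-cell-fraction estimation,
  and embryo positivity calls at the 1:10,000 detection limit.

A `synthetic_data` module (`naivebench.simulate`) generates every input with
the statistical structure the analyses assume — negative-binomial counts with
family polarization, stage-marker embryo matrices, binomial bisulfite calls
with designed DMR trajectories, allelic SNP counts, coupled TE-gene
expression, ChIP tracks, and qPCR dilution plates — with truth tables
sufficient to score every downstream classification. Named presets
(`imprint_4iLA`, `imprint_5iLA`, `methylome_global`, `concordance_morula`,
`concordance_epiblast`, `default`) pin the parameters used by the acceptance
suite.

## CLI

```sh
naivebench simulate --preset imprint_4iLA --seed 1 --out sim/
naivebench imprint --primed sim/allc_primed.tsv --naive sim/allc_naive_4iLA.tsv \
    --reprimed sim/allc_reprimed.tsv --dmrs sim/dmrs.bed --out imp/

naivebench simulate --preset default --seed 1 --out sim2/
naivebench te-de --counts sim2/te_counts.tsv --sheet sim2/samples.csv \
    --annotation sim2/te_annotation.tsv --out de/

naivebench run --config config.yaml        # full pipeline
```

The pipeline config is YAML: a `seed`, an `outdir`, optional `thresholds`
overrides, and one section per stage (`te_de`, `concordance`, `te_gene`,
`methylome`, `allelic`, `profile`, `chimera`), each naming a preset. Missing
sections are skipped and noted; the JSON summary is byte-identical for a
fixed config and seed. Formats are plain text throughout: counts as TSV,
annotations as BED (0-based half-open) or TSV, methylation calls as
allc-style TSV (1-based positions), sample sheets as CSV, coverage tracks as
bedGraph-like TSV.

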
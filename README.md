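# memoryscan

Chronic inflammation leaves a lasting mark on fibroblast-like synoviocytes
(FLS), the stromal cells of the joint synovium: gene-expression and
chromatin-accessibility changes induced by tumor necrosis factor (TNF)
persist even after the cells are removed from the inflammatory environment.
`memoryscan` is a pipeline for identifying the genes that carry this
long-term inflammatory memory from bulk RNA-seq counts and
ATAC-seq/DNase-seq peak files. It is aimed at computational biologists
integrating short-term cytokine-stimulation experiments with chronic-disease
models across mouse and human.

The pipeline has four stages:

1. **Normalization** — reads per kilobase of exon model per million mapped
   reads, RPKM(g, s) = c(g, s) · 10⁹ / (N(s) · L(g)); transcripts with
   RPKM ≥ 3 count as significantly present.
2. **Replicate-free differential expression** — the Audic–Claverie test.
   Given x reads for a gene in a library of N₁ mapped reads, the posterior
   predictive for its count y in a second library of N₂ reads is

       p(y | x) = r^y (x + y)! / ( x! y! (1 + r)^(x+y+1) ),   r = N₂/N₁,

   a negative binomial in y. Two-sided p-values double the smaller tail;
   Benjamini–Hochberg step-up controls the FDR per contrast; a call
   requires ≥ twofold RPKM change and q < 0.05.
3. **Peak annotation** — a peak annotates a gene when it overlaps the
   half-open window [TSS − 5 kb, TSS + 5 kb) by at least 1 bp (BED 0-based
   half-open coordinates throughout).
4. **Memory cascade** — sustained activated genes (mSAGs) are chronic-up
   genes also up in ≥ 1 short-term exposure (mSRGs analogously for down);
   the epigenomically concordant subset additionally carries accessible
   chromatin near the TSS in *both* short-term and chronic peak sets; hSAGs
   / hSRGs are their human orthologs changed in the same direction at both
   human TNF time points. Every step reports numerator, denominator and
   percentage.

A synthetic-data module generates complete studies (counts, annotation,
peaks, ortholog map) with planted gene classes, so the whole pipeline is
testable at desk scale without any sequencing data.

## Worked example

```sh
memoryscan simulate --out demo --seed 42 --n-genes 300
memoryscan run --config demo/config.yaml --out demo_run
```

prints (output of the commands above):

```
sustained_up: 15 of 21 (71.4%)
sustained_down: 9 of 9 (100.0%)
epi_up: 14 of 15 (93.3%)
epi_down: 5 of 9 (55.6%)
human_up: 4 of 14 (28.6%)
human_down: 0 of 5 (0.0%)
human_timepoint_overlap_up: 15 of 15 (100.0%)
human_timepoint_overlap_down: 4 of 4 (100.0%)
```

Reading the cascade: of 21 genes upregulated under chronic TNF, 15 were
also up in at least one short-term exposure (the mSAGs — here exactly the
15 planted sustained-activated genes); 14 of those had accessible chromatin
within 5 kb of their TSS in both conditions; 4 survived the human
conservation filter as hSAGs. `demo_run/` holds every intermediate:
per-contrast DE tables, TSS-distance profiles, one gene-list file per
cascade set, `overlap_summary.json`, and a run log with in/out counts at
every filter. The same stages are available as library functions
(`memoryscan.call_differential`, `memoryscan.assign_peaks_to_tss`,
`memoryscan.classify_memory`, ...) and as individual subcommands
(`normalize`, `de`, `annotate-peaks`, `classify`, `report`) that compose to
the same result.

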
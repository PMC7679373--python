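# Methods

## Statistical model

### Expression and presence

Counts are normalized to reads per kilobase of exon model per million
mapped reads: RPKM(g, s) = c(g, s) · 10⁹ / (N(s) · L(g)), where L(g) is the
summed exon length of the gene model and N(s) the total mapped reads of the
sample. N(s) is taken from a sidecar JSON when supplied, else from the
column sum; in real data mapped reads exceed gene-assigned reads, which is
why the override exists. A transcript is *significantly present* when
RPKM ≥ 3, inclusive at the boundary. A gene enters a contrast when present
in at least one of the two samples — the permissive rule, chosen so genes
induced from zero remain testable; requiring presence on both sides would
silently discard exactly the induction events the cascade looks for.

### Replicate-free differential test

For a gene with count x in a library of N₁ mapped reads, the posterior
predictive distribution of its count y in a second library of N₂ reads
(flat prior on the underlying rate) is

    p(y | x) = r^y (x + y)! / ( x! y! (1 + r)^(x+y+1) ),   r = N₂/N₁,

which is NB(x + 1, 1/(1 + r)) in y. The implementation evaluates log p via
log-gamma. Two-sided p-values double the smaller of the inclusive tails,

    p = min(1, 2 · min(P(Y ≤ y | x), P(Y ≥ y | x))),

capped at 1. Tails are obtained by direct summation of the pmf on
whichever side carries less than half the mass (the other side via the
complement plus the point mass), with chunked summation past the mode to a
relative tolerance of 1e-12 — this bounds accumulated floating error
without special functions. An alternative two-sided policy (sum of all
outcomes no more likely than the observed one, `ac_test_minlike`) is
available behind a flag; tail doubling is the default because it is the
conservative and the more widely reported convention.

A subtlety worth recording: with *inclusive* tails on both sides the
p-value is not exactly invariant under exchanging (x, N₁) with (y, N₂).
The regularized-incomplete-beta identity P(X′ ≤ x | y, 1/r) = P(Y > y | x, r)
makes everything cancel except the observed-point masses, so the two
orientations can differ by up to one pmf term per side (a factor ~2 in
extreme tails). Exact exchange symmetry would require a strict upper tail,
which is anti-conservative; we keep inclusive tails and treat the exchange
property as holding up to the point-mass bound (tested as such).

Fold change is computed on the RPKM scale with a pseudocount of 0.1 added
to numerator and denominator — genes induced from zero get finite, large
fold changes rather than infinities; 0.1 RPKM is far below the presence
floor so it never flips a call for expressed genes. A call requires both
the fold cut-off (≥ 2, or ≤ 1/2 for down) and significance. Significance
defaults to the Benjamini–Hochberg-adjusted q < 0.05 — the conservative
reading when a raw-p threshold and an FDR correction are specified
together — with raw-p thresholding behind `use_adjusted=False`. BH is the
standard step-up: q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j, capped at 1, stable in the
input order.

Replicates, when present, are pooled by summing counts and library sizes
per condition before testing: the test is defined on two pooled libraries
and has no replicate-aware variance model (by design; that is what
negative-binomial GLMs are for, and out of scope here).

### Peak-to-gene assignment

Coordinates are BED 0-based half-open throughout, including the TSS window
[TSS − W, TSS + W) with W = 5000 bp by default, clipped at zero. A peak
annotates every gene whose window it overlaps by ≥ 1 bp — windows of
neighbouring genes may overlap and a peak may annotate several genes. The
indexed implementation (per-chromosome interval tree) is contractually
identical to the naive all-pairs scan, which is kept in the package as the
cross-check oracle. TSS-distance profiles measure from the narrowPeak
summit when present, else the interval midpoint (floor of (start+end)/2),
signed so that positive means downstream in transcript orientation; the
"unique" profile mode keeps only the nearest gene per peak, matching how
such plots are usually drawn (one dot per peak).

### The memory cascade

* mSAG = chronic_up ∩ (∪ over short-term timepoints of up); mSRG likewise
  for down. "At least one short-term exposure" is the default; an
  all-timepoints intersection mode exists for sensitivity analysis.
* epi-filtered subsets intersect with the genes annotated by peaks in
  *both* the short-term and the chronic accessibility sets.
* hSAG/hSRG: orthologs (explicit two-column map; at most one human symbol
  per mouse gene) that are differential in the same direction at both
  human time points. Direction must be conserved; genes flipping direction
  simply fail the intersection.
* Percentages are numerator/denominator · 100 with half-up rounding at a
  configurable precision (integer or one decimal); a zero denominator
  reports as undefined, never as 0. For the human cross-timepoint overlap
  step the denominator is the union of the two human DE sets — the natural
  "tested in either" universe; published analyses of this design report
  denominators that do not correspond to any simple set combination, so no
  attempt is made to mimic a particular one.

## Synthetic studies

The generator emulates the study design end-to-end: mouse FLS under
short-term TNF (16/24/48 h against one untreated control), a chronic-TNF
condition with its own control, human RA-FLS under TNF at 8 and 24 h, one
accessibility peak set per mouse condition, and a 1:1 mouse→human ortholog
map (Title-case symbol → upper-case). Each gene carries one planted class;
class effects are multiplicative on the expected count:

| class | short-term | chronic | human (if conserved) |
|---|---|---|---|
| sustained_activated | ×f | ×f | ×f at both timepoints |
| transient_activated | ×f | — | ×f |
| sustained_repressed | ÷f | ÷f | ÷f |
| transient_repressed | ÷f | — | ÷f |
| chronic_only | — | ×f | ×f |
| null | — | — | — |

Counts are Poisson around μ(g, s) = rpkm(g) · L(g) · N / 10⁹ (negative
binomial with variance μ + αμ² when dispersion α > 0). Key defaults and
why:

* `n_genes = 2000`, `fold_change_active = 4`, `library_size_per_sample = 1e7`:
  a desk-scale design with clearly detectable effects at realistic depth.
* `class_fractions`: null-dominant (77%), with differential classes at a
  few percent each — the order of magnitude of DE-gene counts relative to
  expressed genes in the emulated study.
* baseline expression log-uniform on [3, 500] RPKM: spans two orders of
  magnitude of expressed genes while keeping every gene above the presence
  floor at baseline, so class recovery measures the test rather than the
  floor.
* `epi_concordance`: 0.723 for sustained activated and 0.523 for sustained
  repressed — the concordant fractions observed in the emulated study —
  0.4 for other differential classes, 0.2 for null. Non-concordant genes
  receive a peak in one set only or neither, equally likely.
* `human_conservation`: 52/141 ≈ 0.37 (sustained activated) and
  7/34 ≈ 0.21 (sustained repressed), the observed conservation rates;
  0.3 for other differential classes; 0 for null. Non-conserved orthologs
  are generated as null rather than oppositely regulated — the simplest
  model consistent with direction-conserved filtering.
* TSS spacing ≥ 20 kb: neighbouring 5-kb windows never overlap, so the
  planted concordance flags translate exactly into annotated-gene sets.
  Background peaks (20% of n_genes per set) are placed ≥ 50 kb from any
  TSS and can never annotate a gene.
* one library per condition: the test is replicate-free; replicate columns
  can be requested and are pooled by summation downstream.
* All library sizes equal the configured value (mapped reads, not the
  column sum), so planted fold changes survive normalization exactly.

Determinism: the scenario seed feeds a seed sequence split into four
independent streams (annotation, truth, counts, peaks); identical
scenarios produce byte-identical files.

What the generator does **not** emulate: GC/length bias, mappability
artifacts, fragment-level ATAC signal structure, correlated replicates,
many-to-many orthology, compositional shifts in library size between
conditions, and genes oppositely regulated between species. Passing tests
therefore demonstrate correctness of the statistics and the cascade logic
under the generating model, not robustness to those real-data features.

## Problem sizes used in the test and acceptance runs

Synthetic checks run at 2000 genes (planted-recovery, three seeds), 5000
genes (type-I calibration), and 100–400 genes for IO/pipeline/determinism
contracts; the interval-assignment oracle uses 20 instances of 1000 peaks
× 200 genes. These sizes give stable Monte-Carlo margins (binomial SE
below the asserted tolerances) at interactive runtimes.

## Known limitations

* The Audic–Claverie test models sampling noise only; with biological
  replicates available, a dispersion-aware model is preferable — pooling
  here follows the replicate-free design.
* Presence-in-either filtering plus BH is applied per contrast; calls are
  not jointly corrected across the six contrasts of a full run.
* The ortholog map is functional (≤ 1 human symbol per mouse gene);
  many-to-many homology must be resolved upstream.
* Percentages reported by different analyses of the same design can differ
  through denominator conventions; this package always reports both counts
  alongside every percentage so the convention is auditable.
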
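# Methods

## Pipeline model

The analysis treats a staged differentiation time course (ES → DE →
organoids from day-5/7/10 spheroids) as a non-negative matrix
factorization problem. After FPKM normalization, low-expression
filtering and per-gene mean normalization, the matrix `V` (genes ×
samples, every row mean 1) is decomposed as `V ≈ WH`. Each column of `W`
is read as a gene expression program and each row of `H` as that
program's activity across samples. The model's assumptions are the usual
NMF ones: expression is an additive, non-negative mixture of a small
number of parts, and the number of parts `k` is known. `k` defaults to
the number of distinct stages in the design, since the question being
asked is precisely whether each stage carries its own program; it is
overridable for exploratory use.

### Normalization

`FPKM_gs = c_gs · 10⁹ / (L_g · T_s)`. The mapped-read totals supplied
with the counts are used when available; column sums are the fallback.
The low-expression filter discards transcripts whose maximum FPKM over
samples is *strictly* less than the threshold (default 1), so a row
whose maximum is exactly 1.0 is retained — the boundary reading of a
"less than one" rule. Filtering precedes mean normalization; rows are
whatever identifier the input uses (no transcript-to-gene collapsing).
When a gene-class subset is requested (e.g. DNA-binding proteins from
PFAM annotations), normalization is done on the full filtered matrix
first and the subset taken afterwards, so the class choice does not
change each gene's normalizer; this is configurable by simply reordering
the calls.

### Factorization

Lee–Seung multiplicative updates on the squared Frobenius error, with a
KL-divergence variant behind `objective="kl"`. Initialization is
uniform-random, scaled by `sqrt(mean(V)/k)` so the initial product is on
the scale of `V`. Denominators carry an epsilon of 1e-10; convergence is
declared when the relative objective decrease falls below `tol=1e-6`,
with a hard cap of `max_iter=2000` sweeps. The objective trace is
recorded every sweep and validated as non-increasing at construction
time (with 1e-9 relative slack for floating-point noise). Ten restarts
are run by default from consecutive seeds; "best" means lowest final
reconstruction error, ties broken by lowest seed.

Program membership uses the threshold `mean + 2·SD` of the program's
loading column, with membership *strictly* above the threshold — a
degenerate all-equal column (SD 0) therefore yields an empty, flagged
program rather than a full one. SD is the population SD (ddof 0) by
default with the sample SD behind `sd_kind="sample"`; the choice matters
only in the third decimal for genome-scale columns. Stage assignment
gives each program the stage with the highest mean `H` coefficient and
flags the program non-specific when the top stage's mean is under twice
the runner-up's (ratio configurable).

### Enrichment

Upper-tail hypergeometric probability `P(X ≥ x)` (over-representation;
`x = 0` gives exactly 1). The universe defaults to the genes surviving
the FPKM filter; a variant intersecting with the union of literature-set
genes is available, because the right universe is a judgment call.
Raw p-values are the headline output; Benjamini–Hochberg adjustment is
an optional extra column. Sets smaller than 10 genes after universe
restriction are flagged rather than excluded, since very small sets
support only fragile conclusions. Gene matching is exact-string; mouse
sets must be pre-mapped to the matrix's identifier space.

### qRT-PCR

`AU = 2^(Ct_housekeeping − Ct_gene) × 10,000`; equal Ct gives exactly
10,000 and each extra cycle halves the value. Technical replicates are
averaged on the AU (linear) scale rather than the Ct scale, matching how
the values are plotted; the difference is second-order for small
replicate spread. Group comparison is classical one-way ANOVA
(`F = MS_between/MS_within`, df `(k−1, N−k)`), or a pooled-variance
unpaired t-test for two-group designs (Welch behind a flag). Stars
follow the usual convention (\*, \*\*, \*\*\*, \*\*\*\* at 0.05, 0.01,
0.001, 0.0001) with no cross-gene multiplicity correction, matching how
such panels are conventionally annotated.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* of a staged bulk RNA-seq
experiment: 5 stages with replicates (default 3 each; a
(8, 8, 9, 9, 8) split reproduces a 42-sample study layout), a
genome-scale gene list, and per stage a disjoint 200-gene block whose
expected expression is `baseline_mean × fold_change` in that stage's
samples and `baseline_mean` elsewhere. Counts are negative binomial
(variance `μ + αμ²`, dispersion α = 0.1 by default; a lognormal
alternative sits behind `count_model="lognormal"`). Gene lengths are
uniform on 500–5000 bp so FPKM differs from CPM, and per-sample
lognormal(0, 0.2) size factors make the depth correction consequential.
Defaults — 2000 genes, 200-gene programs, fold change 8, baseline mean
50 — give a clearly detectable but noisy signal at bulk-RNA-seq-like
dispersion.

Literature-style sets keep a chosen fraction of each planted program and
pad with uniform fillers from the rest of the universe (so filler
collisions with planted genes occur at chance rates); a fully random
decoy set disjoint from all programs acts as the colonic negative
control. At `match_fraction=0` the matched sets are plain uniform draws,
which makes the enrichment null exact.

What the generator does *not* emulate: correlated gene modules beyond
the planted blocks, gradual (rather than block) stage transitions,
shared genes between stages, batch effects, length-dependent counting
bias, or transcript-level ambiguity. Passing tests therefore show the
pipeline recovers the signal it is designed for under realistic noise;
they do not show robustness to confounders absent from the simulation.

The qPCR generator fixes the housekeeping Ct (default 20) and puts all
noise (Gaussian, default SD 0.25 cycles) in the gene channel, so AU
variance is attributable to a single source.

## Numerical and design choices

- "Highest scoring factorization" is interpreted as lowest reconstruction
  error; with a Frobenius objective the two phrasings coincide.
- Strict inequalities at both thresholds (filter boundary kept, program
  membership strictly above) are deliberate and documented above.
- Heatmaps take the top-`n` member genes per program by loading (an
  objective stand-in for hand curation), min–max scale each row to
  [0, 1] for display, and always write a TSV sidecar of the plotted
  values; assertions run against the sidecar, never pixels.
- The full pipeline is deterministic under fixed seeds: reruns are
  bit-identical, which is asserted by hashing output files.
- Problem sizes in the test-suite's end-to-end checks (2000 genes × 15
  samples, 10 restarts, 10 generator seeds) were chosen as the smallest
  configuration at which the planted-program recovery question is
  non-trivial; the whole suite runs in well under a minute.

## Known limitations

- No automatic rank selection (cophenetic correlation / consensus
  clustering); `k` must be supplied or defaulted from the design.
- No ortholog mapping; cross-species gene sets must be pre-translated.
- No batch correction, TPM/DESeq-style size factors, or GSEA-style
  rank enrichment — the scope is deliberately the factorization +
  overlap pipeline and its qPCR companion.
- Multiplicative updates converge to a local optimum; the replicate
  mechanism mitigates but does not eliminate initialization dependence.
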
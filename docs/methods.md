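# Methods

## Model and procedure

`surfprofiler` screens for tumor-selective cell-surface transcripts with
a deliberately simple two-group model on the log2 scale. Expression
arrives as non-negative RSEM-style abundance estimates and is transformed
gene-wise as `x = log2(v + 1)`; the pseudocount of 1 maps zero to zero
and is configurable. All downstream statistics treat these log2 values as
approximately Gaussian within a group — the standard working assumption
for t-tests on log-transformed bulk RNA-seq abundances.

Two contrasts are supported, sharing one statistical engine:

1. **Lineage contrast** — tumor vs patient-matched normal samples within
   one cancer lineage. The cohort is built by pairing, per patient,
   exactly one primary tumor with one normal sample; metastatic samples
   are excluded by default, and lineages with fewer than `min_pairs`
   (default 10) complete pairs are refused. Tumors without a matched
   normal are kept aside (`tumor_only`): they contribute nothing to the
   lineage contrast but do take part in the mutation contrast, mirroring
   the asymmetry between matched-pair and annotated-tumor cohort sizes in
   real multi-omic data.
2. **Mutation contrast** — mutant vs wild-type tumors within a lineage,
   where mutant status means carrying at least one variant in the chosen
   gene that survives the consequence filter: truncating variants
   unconditionally, missense variants only with SIFT < 0.05 or
   PolyPhen-2 > 0.85. The inequalities are strict and a missing score
   never qualifies, so boundary and unannotated variants fail closed.
   Normal samples are not used in this contrast.

For each gene, the effect size is `log2Δ`, the difference of group mean
log2 expression (bits), and significance comes from a two-sided
two-sample Student's t-test. The default is the pooled-variance form; a
Welch variant (`welch=True`) and, for the lineage contrast, a paired test
on per-patient differences (`paired=True`) are provided. The pooled
unpaired test is the default even though lineage samples are paired,
because `log2Δ` is defined as a difference of group means and the default
test should match the statistic it accompanies; the paired option is the
statistically stronger alternative when per-patient baselines dominate.

Hits satisfy `log2Δ > min_log2_delta` (default 1.0) **and**
`p < max_p` (default 0.01), strict on both sides, restricted to the
surface gene set unless `surface_only=False`. The threshold applies to
the signed `log2Δ` by default — the screen targets over-expression, since
an ADC antigen must be present, not absent, on the tumor — with an
`absolute` flag for symmetric selection. Raw p-values are the selection
statistic; an optional Benjamini–Hochberg column (statsmodels) is
reported without altering hit calls, so default behaviour is comparable
across runs while the corrected values are available for stricter use.

## Numerical choices

- **Degenerate variance.** When both groups have zero sample variance,
  the t-statistic is undefined. Equal means yield an undefined p (written
  `NA`, never a hit); unequal means yield the smallest positive double as
  a sentinel, flagged in the result, so noise-free synthetic inputs sort
  as maximally significant instead of crashing. Volcano builders cap
  −log10(p) at 300 to keep the sentinel finite on screen.
- **Determinism.** Output row order is a pure function of content
  (descending |log2Δ|, ties by gene label; hits by descending log2Δ).
  Floats are serialised with `repr`, which round-trips doubles exactly
  and is locale-independent. SVG rendering pins matplotlib's hash salt
  and omits the date stamp, so re-renders are byte-identical.
- **Ties and duplicates.** A patient with several primary tumors (or
  normals) in one lineage keeps the lexicographically smallest sample ID
  with a logged warning — a deterministic tie-break where the data leave
  the choice open. Waterfall ranking breaks expression ties by sample ID.
- **Quantiles.** Box-plot five-number summaries use linear interpolation
  between order statistics (numpy default).
- **Gene matching.** Across expression, mutation and gene-set files,
  genes match by symbol first with Entrez id as fallback; TCGA
  `SYMBOL|ENTREZ` row IDs parse into both parts, and `?` symbols keep
  only the Entrez id.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the biology of RNA-seq: per-gene normal-sample expression is drawn
i.i.d. Gaussian on the log2 scale (default baseline 8 bits, SD 1 bit —
typical of a moderately expressed gene in RSEM-quantified bulk data),
tumor samples add planted lineage deltas, and designated mutant tumors
add planted mutation deltas on marker genes. Values are exported on the
raw scale as `2^x − 1`, the exact inverse of the pipeline's
normalisation, so generated bundles enter through the same readers as
real data. Mutation records are constructed so the consequence filter's
outcome is known by construction: qualifying missense variants draw
SIFT ~ U(0, 0.05), decoy records on wild-type tumors draw
SIFT ~ U(0.05, 1) with PolyPhen-2 ~ U(0, 0.85) or are synonymous, and
truncating variants carry no scores.

What the generator does **not** model: gene–gene correlation, per-patient
baselines shared between a patient's tumor and normal sample,
mean–variance dependence, library-size effects, or count noise. Passing
tests therefore demonstrate that the pipeline's bookkeeping and
statistics are correct under its own assumptions — they do not certify
calibration on real cohorts, where correlated genes and heavier tails
inflate false-positive rates relative to the Gaussian ideal. The paired
t-test option exists precisely because real matched samples violate the
independence the default test assumes.

The packaged default scenario (`default_spec`) is a three-lineage cohort
(29/20/15 pairs), 1,200 genes of which 100 are surface, one planted
2-bit lineage-specific surface gene per lineage, and an STK11-style
mutation signature in LUAD: 6 mutant tumors with marker effects of 2.76,
4.74 and 1.55 bits — the scale of strong mutation-linked surface markers
in lung adenocarcinoma. These sizes keep every end-to-end run in seconds
on one CPU while leaving the 6-vs-23 contrast genuinely small-sample.

## Verification strategy

The statistical engine is checked against independent oracles rather
than against itself: a hand-coded pooled-variance t-test whose p-value
comes from the incomplete-beta form of the t CDF (agreement to 1e-12),
and the exact permutation null of the t statistic obtained by full
enumeration of group assignments at ≤10v10 (Monte-Carlo permutation
estimates agree with the enumeration within binomial error, and the
enumerated null reproduces the t p-values in aggregate across fixtures —
the per-fixture permutation p is conditional on the observed sample and
deviates individually, as it must). Planted-effect recovery, median
false-positive counts, and the null rejection rate at p < 0.01 are
verified over hundreds of seeded cohorts; filter behaviour is verified
exactly on labelled records including the score boundaries.

## Known limitations

- The consequence filter trusts the provided SIFT/PolyPhen-2 annotations;
  there is no re-annotation, transcript-level reasoning, or germline
  filtering beyond what the input table encodes.
- Surface membership is whatever gene set the user supplies; the packaged
  list is a synthetic stand-in for the GO:0009986 membership (real
  surface/ADC symbols padded with placeholders to 519 entries) intended
  for pipeline testing, not for biological interpretation.
- Raw p-value selection (the default) does not control the
  transcriptome-wide false discovery rate; the BH column should be
  preferred when hit lists feed expensive follow-up.
- One sample per patient per arm: multi-aliquot patients are collapsed by
  the deterministic tie-break rather than modelled hierarchically.
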
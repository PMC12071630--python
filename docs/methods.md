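# Methods

## Dosage-adjusted ASE model

The unit of analysis is the allele pair: one A-subgenome gene matched to
its B-subgenome homolog. In an ABB triploid the B side of the measurement
aggregates two haplotypes (reads are mapped against one collapsed B
reference gene), so a pair with no regulatory imbalance is expected at
B:A = 2:1. A `PloidyModel(copies_a, copies_b, fold_factor)` turns copy
numbers into calling thresholds: with dosage ratio r = copies_b/copies_a
and fold factor k, the pair is B-dominant when b > k·r·a and A-dominant
when b < (r/k)·a, both inequalities strict; a pair sitting exactly on a
threshold is balanced. Comparisons are multiplicative, never ratios, so
a = 0 with expressed b is B-dominant and no division-by-zero guard is
needed. At copies (1, 1) this is exactly the standard diploid 2-fold rule
(verified against a direct implementation in the test suite).

Classification uses replicate-mean RPKM per stage, matching the
granularity at which such studies report per-stage allele values;
per-replicate voting is deliberately not attempted. Pairs whose combined
stage-mean RPKM falls below `min_expression_rpkm` (default 1) are
`NOT_EXPRESSED` and excluded from the ASE denominator — the floor avoids
0/0 artifacts and is configurable because published screens rarely state
one. The genome-wide ASE percentage is
100·(B-dominant + A-dominant)/pairs-tested, reported to one decimal.
On the published FJ counts this reproduces 27.2% at 3 d; at 6 d the
computed value is 22.1% ((1512+1900)/15415 = 22.13%) where the source
summary rounds to 22.2% — the package reports the computed value.

## Differential-expression gate

Only differentially expressed allele pairs are classified: a pair enters
when its A and/or B member changes at least `deg_fc_threshold`-fold
(default 2, inclusive) at BH FDR < `deg_alpha` (default 0.05) in any
non-baseline stage versus the 0-DPH harvest reference. The engine is a
re-implementation of the classic DESeq-v1 scheme rather than a wrapper, so
the pipeline is self-contained and each piece is testable:

- **Size factors**: median over all-positive genes of count/geometric-mean.
  Note the exact equivariance: scaling one library by c multiplies its
  factor *relative to the others* by c (the product of factors is
  invariant), leaving normalized counts unchanged up to a constant common
  to all samples.
- **Dispersion**: per-gene method of moments on normalized counts
  (pooled within-group variance, shot-noise corrected), then a parametric
  trend alpha(mu) = a0 + a1/mu fitted by iteratively reweighted least
  squares. The default `"shrink"` mode blends gene and trend estimates on
  the log scale, weighted by residual degrees of freedom against a prior
  weight of 10 — at 3-vs-3 replicates the trend dominates, which keeps the
  exact test near-nominal (measured type-I error ~0.06 at alpha = 0.05 in
  the suite's null simulation), whereas the historical max-sharing mode is
  markedly conservative (~0.03) and raw gene-wise estimates are
  anti-conservative (~0.11). Modes `"fit"`, `"gene"` and `"max"` are
  selectable.
- **Exact test**: conditional on a gene's grand total across both groups,
  the two-sided p-value sums the probabilities of all splits at most as
  likely as the observed one, each group total NB with moment-matched
  mean and variance. Totals above 10^6 switch to a normal approximation;
  all-zero genes get p = 1 by convention.
- **BH adjustment** is implemented directly (step-up, monotone); the test
  suite checks it against statsmodels and a brute-force min-over-suffix
  oracle.

When the input carries only RPKM (no raw counts), a fold-change-only
fallback screens on stage-mean RPKM with p and q undefined; this exists
because public expression tables are often RPKM-only, and it is clearly
flagged in the output.

Contrasts are each later stage against the harvest baseline. Requiring DE
in a second cultivar is supported as an off-by-default intersection flag
(`require_both_cultivars_deg`); it defaults off because the ASE analysis
itself is single-cultivar and the intersection variant cannot be
validated against published per-stage counts.

## Family tables and enrichment

Family annotation attaches to the allele pair (the tables count pairs, not
individual subgenome genes). A family row at a stage reports the DEG-pair
count, A-dominant and B-dominant counts, and the ASE ratio
100·(A-dom + B-dom)/n_DEGs to two decimals; the denominator is the
family's full DEG count rather than the expressed subset, which is the
convention that reproduces published family tables exactly. Pathway
summaries report the min–max ratio over the member families at all stages,
to one decimal.

Enrichment is a generic over-representation test on user-supplied term
maps (GO/KEGG databases are deliberately out of scope): upper-tail
hypergeometric p per term, BH across all terms of one map, Rich Factor
k/K. The default universe is the annotated DEG pairs. The discrete test is
slightly conservative by construction; the suite's permutation sanity
check measures ~0.04 rejection at p < 0.05 for random selections.

## qPCR and physiology statistics

Relative expression is 2^−(Ct_target − Ct_reference) (the 2^−ΔCt
convention against a reference assay such as a ribosomal-protein gene);
a ΔΔCt of d between samples is exactly an expression ratio of 2^−d.
Associations with physiology series (ethylene evolution, starch content)
are Spearman correlations on stage means with average ranks for ties; for
n ≤ 8 stages the two-sided p-value enumerates all n! rank permutations
exactly, otherwise the t approximation is used. Amplification-efficiency
correction and replicate-level pairing are out of scope.

## Synthetic data generator

The generator draws what the analysis assumes, nothing more:

- per-pair baseline expression log-normal (`baseline_mean_log_mu`,
  default log 100 "reads per kb"; sigma 1.0), expected counts =
  expression × length/1000 so RPKM ratios recover expression ratios with
  independently drawn member lengths (500–5,000 bp uniform);
- counts negative binomial with common dispersion (default 0.1,
  a conventional bulk-RNA-seq value; the emulated study publishes no
  dispersion or depth figures, so these are configurable, not derived);
- three stages (0/3/6 DPH) × 3 replicates by default, 2,000 pairs
  (scalable to the genome-wide ~25,716);
- injected ASE: configurable fractions of B-dominant and A-dominant pairs
  (default 10% each) placed exactly `ase_effect_multiplier` (default 2)
  beyond the corresponding threshold, i.e. true B/A of 8 and 0.5 under the
  ABB defaults, constant across stages;
- DE trajectories: fractions of pairs (default 10% up, 10% down) with
  |log2FC| ~ |N(2.5, 0.5)| ramping linearly from baseline to the final
  stage. DE status is drawn per pair and applied to both members so that
  the injected B/A ratio — and hence the ASE truth class — is
  stage-invariant; truth is still recorded per gene. RPKM uses the
  configured library size (default 10^7) as the mapped-read total.

What the generator does *not* emulate: mapping bias between subgenomes,
GC and length biases beyond the linear length effect, inter-gene
correlation, replicate-specific library composition effects, and outlier
samples. Passing recovery benchmarks therefore demonstrates correctness of
the statistical machinery under the stated model, not robustness to those
real-data artifacts.

Benchmarks at the default configuration (2,000 pairs, fixed seeds; a few
seconds per run): ASE sensitivity and specificity ≥ 0.95 on pairs with
mean counts ≥ 50, DEG recall ≥ 0.9 at |log2FC| ≥ 2.5 with empirical FDR
≤ 0.1, simulated dispersion recovered within 25% at mean counts ≥ 100,
and mean balanced-pair RPKM ratio within ±0.1 of the dosage ratio.

## Numerical and interface choices

- All tables are single-header TSV with `#` comments; identifiers are
  opaque strings (subgenome comes from an explicit column, never from
  id prefixes). Malformed input raises a typed error; nothing is dropped
  silently (unresolvable annotation ids are retained and reported).
- Exact-test log-probabilities are summed with logsumexp; the
  "at most as likely" comparison uses a 1e-12 slack to absorb float
  noise at probability ties.
- `top_terms` sorts by ascending q, ties broken by descending Rich Factor
  then term id, truncating to 20 — mirroring the usual top-20 enrichment
  panel.
- The pipeline writes a manifest (config, seed, thresholds, input SHA-256
  checksums); reruns on identical inputs are byte-identical, which the
  suite asserts.
- Problem sizes in the test suite (2,000 pairs, 2,500 null genes) are the
  package's benchmark defaults: large enough for stable rates, small
  enough to keep the whole suite under a minute.

## Known limitations

- The NB exact test approximates replicate structure through group totals
  (as DESeq v1 did); designs with covariates need a GLM engine, which is
  out of scope.
- The dosage model treats the two B haplotypes as one collapsed gene; it
  cannot detect imbalance *between* the two B copies.
- The RPKM-only DEG fallback has no error control — it is a screen, not a
  test.
- With a single replicate per stage, dispersion falls back to blind
  estimation across all samples and the test becomes conservative.
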
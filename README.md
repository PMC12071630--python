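# triploid-ase

Dosage-aware allele-specific expression (ASE) analysis for triploid
interspecific hybrids, built around the ABB banana case: a genome carrying
one *Musa acuminata* (A) and two *Musa balbisiana* (B) chromosome sets.

## The problem

In a diploid heterozygote the two alleles of a locus are expected to be
expressed 1:1, and the conventional ASE rule calls imbalance when one allele
exceeds the other more than 2-fold. In an ABB triploid the *balanced*
expectation for a subgenome allele pair is instead B:A = 2:1, because two B
copies face one A copy. Applying the diploid rule unchanged would call
dosage itself "imbalance". This package re-centres the threshold on copy
number: for copy numbers (c_A, c_B) and fold factor k, with dosage ratio
r = c_B / c_A,

    B-dominant   iff  B > k·r·A     (ABB, k = 2:  B > 4A)
    A-dominant   iff  B < (r/k)·A   (ABB, k = 2:  B < A)
    balanced     otherwise

applied to replicate-mean RPKM per ripening stage. Setting (1, 1) recovers
the standard diploid 2-fold rule exactly.

Around this classifier the package provides the full analysis pipeline for
a postharvest ripening series:

- **deg_calling** — a self-contained DESeq-v1-style gate (median-of-ratios
  size factors, method-of-moments NB dispersion with trend shrinkage, NB
  exact test, Benjamini–Hochberg FDR): an allele pair enters the ASE
  analysis when either member changes ≥ 2-fold at FDR < 0.05 versus the
  0-days-post-harvest baseline;
- **ase_calling** — dosage-adjusted classification and genome-wide per-stage
  summaries (counts of B-dominant / A-dominant / balanced pairs and the ASE
  percentage);
- **family_summary** — per-gene-family ASE-ratio tables
  (100 · (A-dominant + B-dominant) / n_DEGs) and pathway min–max ranges;
- **enrichment** — hypergeometric over-representation of ASE sets against
  user-supplied term maps, with BH q-values and the Rich Factor
  (selected-in-term / annotated-in-term);
- **validation_stats** — allele-specific qPCR quantification (2^−ΔCt against
  a reference gene) and Spearman rank correlation with physiology series
  (exact permutation p-values at small n);
- **synthetic_data** — a negative-binomial allele-pair simulator with known
  ASE and DE truth (1:2 dosage baseline, stage-ramped fold changes,
  injected imbalance at a configurable distance beyond the thresholds), so
  every stage of the pipeline is benchmarked against ground truth.

## Worked example

```python
import triploid_ase as ta

cfg = ta.SimulationConfig(n_pairs=500, seed=4)
matrix, pairs, truth = ta.simulate_dataset(cfg)
bundle = ta.run_pipeline(ta.PipelineConfig(), matrix, pairs)
print(bundle["genome_summary"].to_string(index=False))
```

prints

```
 stage_dph  n_pairs_tested  n_b_dominant  n_a_dominant  n_balanced  n_not_expressed  ase_percent
         3             105             5            10          90                2         14.3
         6             104             4             7          93                3         10.6
```

Of the 500 simulated allele pairs, 107 passed the differential-expression
gate. At 3 days post-harvest, 105 of those were expressed above the RPKM
floor; 5 were B-dominant (B > 4A) and 10 A-dominant (B < A), i.e. 14.3% of
tested DEG pairs showed allele-specific expression. The simulator injected
10% B-dominant and 10% A-dominant pairs genome-wide, and DEG status is
drawn independently of ASE status, so roughly one fifth of DEG pairs carry
injected imbalance — consistent with what the classifier reports.

The same analysis runs from the shell on TSV inputs:

```bash
triploid-ase simulate --n-pairs 500 --seed 4 --out sim/
triploid-ase run --expression sim/expression.tsv --design sim/design.tsv \
    --pairs sim/pairs.tsv --out results/
```

Subcommands `deg`, `ase`, `summarize`, `enrich` and `validate` run each
stage standalone on intermediate files.

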
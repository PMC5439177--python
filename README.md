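# kscfs — two-stage gene selection for binary-class expression data

Selecting a small panel of discriminative genes from an expression matrix
with tens of thousands of genes and only tens of samples is a core step in
cancer transcriptomics: classifiers overfit wildly on the full matrix, and
univariate screens return hundreds of mutually redundant genes. `kscfs`
implements a two-stage hybrid for two-class (tumor vs normal) cohorts:

1. **Stage 1 — distribution screen.** Every gene is tested with the
   two-sample Kolmogorov–Smirnov statistic
   `D = max_x |F1(x) − F2(x)|`, the maximum absolute difference between the
   per-class empirical CDFs. A gene passes when `D ≥ D_crit(α)`,
   equivalently `p ≤ α` (exact permutation p-values by lattice-path
   counting). Because D compares whole distributions, the screen catches
   location, scale and shape differences alike — a variance-only signal
   invisible to t or rank-sum tests still registers.
2. **Stage 2 — redundancy removal.** Correlation-based feature selection
   (CFS) searches subsets S of the surviving candidates for the maximum
   merit
   `M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`,
   where `r̄_cf` is the mean gene–class association and `r̄_ff` the mean
   gene–gene association, both measured as symmetrical uncertainty
   `SU(a,b) = 2·I(a;b)/(H(a)+H(b))` over MDL-discretized values. The merit
   rewards class-informative genes and penalizes mutual redundancy; a
   best-first search returns a compact panel.

The package also provides the standard comparison baselines — Wilcoxon and
t filters, mRMR and ReliefF rankers with wrapper forward selection — a
cross-validated linear-SVM (C = 1) evaluation harness with the
repeated-shuffle protocol, loaders for CSV/TSV/ARFF expression tables, and
a synthetic-data generator that plants ground-truth informative, redundant
and noise genes so every stage is testable without external datasets.

## Worked example

```python
from kscfs import generate_synthetic, ks_cfs_select, paper_like_spec, zscore_standardize

ds, truth = generate_synthetic(paper_like_spec(seed=8))   # 2,000 genes, 40+40 samples
z = zscore_standardize(ds)
subset = ks_cfs_select(z, alpha=0.01)
print(len(subset.parent), len(subset))
```

Running `python examples/03_two_stage_selection.py` (the same computation
plus the ground-truth comparison) prints:

```
stage 1 (K-S at alpha=0.01): 53 candidate genes of 2000
stage 2 (CFS):               22 genes, merit 0.895
distinct planted signals recovered: 19/30
noise genes selected: 0
```

Of 2,000 genes the K-S screen keeps 53 candidates; CFS compresses them to a
22-gene panel that still covers 19 of the 30 planted signals (a redundant
near-copy counts toward the signal it copies) with no noise genes. The other
scripts in `examples/` walk through the generator, the univariate screens,
the rankers with wrapper selection, and the five-way method comparison.

A thin CLI wraps the same functions:

```sh
kscfs simulate --preset paper-like --seed 7 -o toy/
kscfs filter toy/data.csv --test ks --alpha 0.01 -o report.tsv
kscfs compare toy/data.csv --methods ks_cfs,cfs,ks,mrmr,relieff -o out/
```

Every command writes a JSON provenance record and is byte-reproducible
under a fixed seed.

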
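# Methods

## Setting and model

The input is a two-class expression matrix: `n` samples (tumor = positive,
normal = negative) by `p` genes, with `p >> n` (thousands of genes, tens to
hundreds of samples). The goal is a compact gene panel that discriminates the
classes. All stages assume the matrix has been Z-score standardized per gene
over all samples pooled — `x ← (x − mean)/sd` with the sample (n−1)
standard deviation. Standardization is deliberately class-blind: scaling
within classes would leak label information into the features before
selection. Constant genes map to all-zero columns and are flagged, not
rejected, because real microarray exports contain flat probes and every
downstream test must tolerate them (they get `D = 0`, `p = 1`, and are never
selected).

## Stage 1: the Kolmogorov–Smirnov screen

For a gene with per-class observations, the empirical CDF of each class is
`F(x) = #(values ≤ x)/n` (right-continuous), and the test statistic is
`D = max_x |F1(x) − F2(x)|`. Both ECDFs are step functions changing only at
observed values, so the maximum is attained at a pooled observation point;
the implementation evaluates exactly those points. D is rank-based:
invariant under any strictly increasing transform of both samples.

**P-values.** The decision `D ≥ D_crit(α)` is applied as `p ≤ α`. The
p-value is computed *exactly* from the permutation null: `P(D_nm ≥ d)`
equals one minus the fraction of monotone lattice paths from `(0,0)` to
`(n,m)` that keep `|i/n − j/m| < d` at every step, computed by an `O(n·m)`
dynamic program with on-the-fly rescaling (counts up to `C(506,253)` stay in
float range) and memoized per `(D, n, m)`. The familiar asymptotic form —
the Kolmogorov survival function at `(√m̃ + 0.12 + 0.11/√m̃)·D` with
`m̃ = nm/(n+m)` — is available behind `method="asymp"` and used
automatically when `n·m > 250,000`. The exact method is the default because
at cohort sizes the asymptotic form is visibly off: at `n = m = 50`,
`D = 0.2` the exact p is 0.2719 while the asymptotic value is 0.2408. The
exact computation was validated against `scipy.stats.ks_2samp(method="exact")`
(agreement to 1e-9 on random instances) and against a 100,000-shuffle
Monte-Carlo permutation oracle.

**Degenerate inputs.** Genes constant in both classes with equal values are
reported as `D = 0, p = 1` and never pass any filter; `α = 1` keeps every
gene (the no-filter baseline), since `p ≤ 1` always holds.

**Baseline filters.** The Wilcoxon rank-sum test reports the midrank sum of
the smaller group with a tie-corrected normal approximation and 0.5
continuity correction (the exact enumeration lives only in the test
oracles); the t test uses the Welch form by default (`equal_var=True`
switches to pooled). Both are two-sided, as is the K-S decision. No
multiple-testing correction is applied anywhere: the screen filters at raw
α by design, and the α-sweep runner exposes how the selected-set size moves
with the level. Selected sets are nested in α by construction.

## Stage 2: correlation-based feature selection

Associations are symmetrical uncertainties `SU(a,b) = 2·I(a;b)/(H(a)+H(b))`
(entropies in bits; `SU = 0` when either input is constant). Expression
values are discretized once per gene by recursive entropy minimization with
the minimum-description-length stopping rule, supervised by the class
labels; a gene for which no cut passes the MDL test collapses to a single
bin and thus has zero class association — this is what makes CFS robust to
thousands of noise genes. Equal-frequency binning (default 10 bins) is
available as an unsupervised fallback.

The merit of a subset S of k genes is
`M(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`; for `k = 1` it reduces to the
gene's class association, and the empty subset scores 0. The search is
forward best-first: an open list of evaluated nodes keyed by merit, the
best unexpanded node expanded by single-gene additions, terminating after 5
consecutive expansions that fail to improve the best merit. Ties break
toward the subset discovered first and genes in original column order, so
the search is deterministic. On candidate sets of ≤ 15 genes the search
provably recovers the exhaustive-subset maximum in all tested instances
(100/100 random datasets).

**What redundancy removal does and does not mean.** The merit is *exactly*
invariant under duplicating an entire subset (substituting the sums shows
`M(S ∪ copy(S)) = M(S)` for perfect copies), so whether a duplicate enters
the optimal subset is decided by the inequality
`(R + r_d)²(k + 2F) vs R²(k + 3 + 2F + 2c_d)` — in words, a duplicate of a
gene whose *estimated* class association sits above the subset average
strictly raises the merit. Two consequences follow. First, noisy near-copies
(which carry some genuinely independent class information) and small-sample
SU estimates (n ≈ 40 per class, where per-gene association estimates
fluctuate by ~±15%) make duplicate retention a near coin flip. Second, with
exact copies and precise association estimates the inequality resolves
against duplication and CFS removes duplicates reliably. The redundancy
tests therefore use exact duplicate pairs (`redundancy_noise = 0`) at 150
samples per class with 12 equal-effect signals: there CFS keeps at most one
member per pair in ≥ 94% of 50 seeded replicates while the K-S filter —
which scores each gene in isolation — keeps both members in every run.

## Ranking baselines

* **mRMR** (difference form): genes are discretized to three levels at
  mean ± sd; the first pick maximizes `I(gene; class)`, each later pick
  maximizes relevance minus mean mutual information with the already-picked
  genes. The quotient form is available behind `variant="miq"`. The raw
  incremental objective is not monotone (mean redundancy can drop when a
  low-redundancy gene enters), so the *reported* scores are its running
  minimum — a valid nonincreasing ranking weight; the rank order itself is
  the raw greedy order. Ties break on original gene order, making the
  ranking independent of candidate input order.
* **ReliefF**: deterministic variant using every instance once; per
  instance, gene weights decrease by the mean range-normalized distance to
  the `k = 10` nearest same-class hits and increase by the
  class-prior-weighted mean distance to the 10 nearest opposite-class
  misses (for two classes the prior weight is 1); inter-instance distance
  is Manhattan over range-normalized values. Subsampling of instances is
  available and seeded.
* **Wrapper forward selection**: walks a ranked list, seeds the subset with
  the top gene, and keeps a later gene only when it *strictly* improves the
  evaluator (cross-validated SVM accuracy by default). Strictness prevents
  unbounded growth under ties.

## Evaluation protocol

Subsets are scored by a linear-kernel SVM with `C = 1` — deliberately an
off-the-shelf component, never tuned — under seeded stratified k-fold
cross-validation (folds reduce with a warning when the smaller class is
smaller than the fold count). The repeated-shuffle protocol reshuffles the
sample order per repeat (seed `base_seed + r`), re-runs the selector on the
shuffled data, cross-validates its subset with the same seed, and averages
accuracies and panel sizes over repeats; a repeat whose selector returns an
empty subset is excluded and flagged. Selection runs once per repeat on the
full shuffled dataset before cross-validation — the conventional protocol in
this literature, which carries a known optimistic selection bias — and a
stricter `select_per_fold=True` mode re-runs selection inside each training
fold; the stricter mode is the methodologically cleaner estimate and the
default is kept only for comparability with standard practice. Accuracies
are reported in percent.

## Synthetic study conditions

The generator plants four gene roles on a standard-normal background:
*shift* genes (class means differ by `shift_effect` within-class sd, default
2.0 — a strong but realistic microarray effect), *scale* genes (equal means,
positive/negative sd ratio `scale_ratio`, default 3 — detectable by a
distribution test, invisible to mean/rank tests and, notably, useless to a
linear SVM), *redundant* genes (a copied informative gene plus independent
noise of sd `redundancy_noise`), and *noise* genes (identical class
distributions). The default conditions (`paper_like_spec`) are 2,000 genes —
20 shift, 10 scale, 15 redundant, 1,955 noise — with 40 samples per class,
matching the scale of small two-class cancer cohorts. Identical spec and
seed give bit-identical data.

What the generator does *not* emulate: heavy-tailed and probe-specific noise
distributions, correlated noise blocks (batch effects), class imbalance
beyond what the spec fields express, and signal effect-size heterogeneity.
Passing tests on these conditions therefore demonstrate algorithmic
correctness and the claimed qualitative orderings, not clinical performance
on real cohorts.

## Quantities reported by `scripts/acceptance.py`

All simulations are seeded from `--seed`; problem sizes are chosen so the
script completes in well under a minute on one CPU.

* Exactness: K-S statistic vs a brute-force pooled-point oracle (1,000
  random instances); CFS best-first vs exhaustive search (100 random
  candidate sets); the rank-sum enumeration oracle (2/252 for fully
  separated 5-vs-5 samples); nested-filter containment violations (0).
* Calibration: K-S rejection rates on 2,000 null genes at 50 samples per
  class — conservative, ~0.03–0.05 at α = 0.05 and ~0 at α = 0.001 because
  the discrete permutation null cannot be rejected at exactly the nominal
  rate.
* Sensitivity: rejection rates on 200 scale-only genes (sd ratio 3); the
  K-S rate exceeds the rank-sum and t rates by ~0.8 absolute.
* Redundancy: duplicate-pair removal/retention rates under the exact-copy
  conditions above.
* Pipeline: planted-signal recall of the two-stage selection at the default
  conditions (typically 0.6–0.75 across seeds, occasionally lower — the
  merit optimum keeps the above-average half of many equal-strength
  signals, so recall fluctuates with the association estimates), mean
  repeated-shuffle accuracy (~100% at these effect sizes), and panel sizes
  for the two-stage selection vs the K-S filter alone (roughly 2x
  compression).

## Known limitations

* The exact K-S p-value assumes no cross-class ties; with heavily tied data
  it is conservative. Standardized continuous expression values make exact
  cross-class ties measure-zero.
* CFS inherits the duplicate-retention edge cases analyzed above; on small
  cohorts a noisy near-copy of a strong gene can legitimately enter the
  merit-optimal panel.
* A linear SVM cannot exploit variance-only signals, so keeping scale genes
  improves recall metrics but not linear-classifier accuracy; with a
  nonlinear classifier the K-S screen's extra sensitivity would matter more.
* The best-first search is exact on small candidate sets but heuristic in
  general; no optimality guarantee exists for hundreds of candidates.
* Runtime of the two-stage selection is dominated by pairwise SU
  computation inside the CFS search and grows with the stage-1 candidate
  count; no particular optimization effort has been spent on it.
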
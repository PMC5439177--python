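"""Simulate a two-class expression matrix with planted structure.

Builds a small cohort (40 tumor + 40 normal samples) in which a minority of
genes carry real between-class differences — mean shifts, pure variance
changes, and noisy near-copies of informative genes — then Z-score
standardizes it, the preprocessing every selection stage assumes.
"""

from kscfs import SyntheticSpec, generate_synthetic, zscore_standardize

spec = SyntheticSpec(
    n_pos=40, n_neg=40,
    n_informative_shift=5, shift_effect=2.0,   # class means differ by 2 within-class sd
    n_informative_scale=3, scale_ratio=3.0,    # equal means, tumor sd is 3x normal sd
    n_redundant=4, redundancy_noise=0.05,      # near-copies of informative genes
    n_noise=50, seed=1,
)
ds, truth = generate_synthetic(spec)
z = zscore_standardize(ds)

print(f"dataset: {ds.n_samples} samples x {ds.n_genes} genes "
      f"({ds.n_pos} positive / {ds.n_neg} negative)")
print(truth.role.value_counts().to_string())
print(f"after standardization every gene has mean ~0 and sd ~1: "
      f"max |mean| = {abs(z.values.mean(axis=0)).max():.2e}")

# The role table is the ground truth selection methods are judged against:
# 'shift' and 'scale' genes are the real signals, 'redundant' genes copy one
# of them (column 'source'), and 'noise' genes carry no class information.
print(truth.head(10).to_string(index=False))
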
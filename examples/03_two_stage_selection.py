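"""The two-stage pipeline: K-S screen, then CFS redundancy removal.

Stage 1 keeps the genes whose class distributions differ at α = 0.01; stage
2 searches subsets of those candidates for the best trade-off between class
association and mutual redundancy (the CFS merit), returning a compact gene
panel. The selection is checked against the generator's ground truth.
"""

from kscfs import generate_synthetic, ks_cfs_select, paper_like_spec, zscore_standardize

ds, truth = generate_synthetic(paper_like_spec(seed=8))
z = zscore_standardize(ds)

subset = ks_cfs_select(z, alpha=0.01)

roles = dict(zip(truth.gene_id, truth.role))
source = dict(zip(truth.gene_id, truth.source))
informative = {g for g, r in roles.items() if r in ("shift", "scale")}
covered = {
    source[g] if roles[g] == "redundant" else g
    for g in subset.gene_ids if roles[g] != "noise"
}
false_pos = [g for g in subset.gene_ids if roles[g] == "noise"]

print(f"stage 1 (K-S at alpha=0.01): {len(subset.parent)} candidate genes of {z.n_genes}")
print(f"stage 2 (CFS):               {len(subset)} genes, merit {subset.params['merit']:.3f}")
print(f"distinct planted signals recovered: {len(covered)}/{len(informative)}")
print(f"noise genes selected: {len(false_pos)}")

# The two-stage panel is several times smaller than the stage-1 candidate
# set while still covering most planted signals; noise contamination is low
# because a noise gene adds class-irrelevant entropy and lowers the merit.
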
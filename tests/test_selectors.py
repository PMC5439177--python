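import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kscfs import (
    CorrelationCache,
    GeneSubset,
    RankedGenes,
    SyntheticSpec,
    cfs_merit,
    cfs_select,
    filter_genes,
    forward_select,
    generate_synthetic,
    mrmr_rank,
    mutual_information,
    relieff_rank,
    relieff_weights,
    symmetric_uncertainty,
    zscore_standardize,
)

from conftest import make_dataset


def contingency_mi_bits(a, b):
    """Oracle: I(a;b) from the joint contingency table, in bits."""
    a, b = np.asarray(a), np.asarray(b)
    mi = 0.0
    n = len(a)
    for va in np.unique(a):
        for vb in np.unique(b):
            pab = np.mean((a == va) & (b == vb))
            if pab > 0:
                mi += pab * np.log2(pab / ((a == va).mean() * (b == vb).mean()))
    return mi


class TestSymmetricUncertainty:
    def test_self_association_is_one(self):
        assert symmetric_uncertainty([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_relabeling_preserves_association(self):
        assert symmetric_uncertainty([0, 0, 1, 1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_independent_factorizing_table(self):
        a, b = [0, 0, 1, 1], [0, 1, 0, 1]
        assert contingency_mi_bits(a, b) == pytest.approx(0.0, abs=1e-12)
        assert symmetric_uncertainty(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_constant_sequence_is_zero(self):
        assert symmetric_uncertainty([3, 3, 3, 3], [0, 1, 0, 1]) == 0.0

    def test_matches_entropy_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 3, 40)
            b = (a + rng.integers(0, 2, 40)) % 3
            ha = contingency_mi_bits(a, a)  # H(a) = I(a;a)
            hb = contingency_mi_bits(b, b)
            expected = 2 * contingency_mi_bits(a, b) / (ha + hb)
            assert symmetric_uncertainty(a, b) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)), min_size=2, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_range(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        su_ab = symmetric_uncertainty(a, b)
        su_ba = symmetric_uncertainty(b, a)
        assert su_ab == pytest.approx(su_ba, abs=1e-12)
        assert 0.0 <= su_ab <= 1.0


class FakeCache:
    """Hand-specified associations for closed-form merit checks."""

    def __init__(self, rcf, rff):
        self.feature_class = np.asarray(rcf, dtype=float)
        self._rff = rff

    def feature_feature(self, i, j):
        if i == j:
            return 1.0
        return self._rff[tuple(sorted((i, j)))]


class TestCFSMerit:
    def test_single_gene_reduces_to_rcf(self):
        cache = FakeCache([0.8], {})
        assert cfs_merit([0], cache) == pytest.approx(0.8)

    def test_perfect_duplicate_pair_keeps_merit(self):
        cache = FakeCache([0.8, 0.8], {(0, 1): 1.0})
        assert cfs_merit([0, 1], cache) == pytest.approx(0.8)

    def test_irrelevant_uncorrelated_gene_lowers_merit(self):
        cache = FakeCache([0.8, 0.0], {(0, 1): 0.0})
        assert cfs_merit([0, 1], cache) == pytest.approx(0.8 / np.sqrt(2))

    def test_empty_subset(self):
        assert cfs_merit([], FakeCache([], {})) == 0.0


class TestCFSSelect:
    def test_predictive_gene_always_kept(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(40, int), np.zeros(40, int)]
        vals = rng.standard_normal((80, 21))
        vals[:, 0] = y * 4 + rng.standard_normal(80) * 0.1  # near-perfect predictor
        ds = make_dataset(vals, y)
        sub = cfs_select(ds, ds.gene_ids)
        assert "g0" in sub

    def test_best_first_matches_exhaustive_on_small_candidates(self):
        """Search correctness: best-first merit equals the max over all
        nonempty subsets of <= 10 candidate genes."""
        agree = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_g = int(rng.integers(4, 11))
            y = np.r_[np.ones(15, int), np.zeros(15, int)]
            vals = rng.standard_normal((30, n_g))
            vals[:, :3] += y[:, None] * rng.uniform(0.3, 2.0, size=3)
            ds = make_dataset(vals, y)
            cache = CorrelationCache(ds, ds.gene_ids)
            best = max(
                cfs_merit(list(s), cache)
                for k in range(1, n_g + 1)
                for s in itertools.combinations(range(n_g), k)
            )
            sub = cfs_select(ds, ds.gene_ids)
            merit = sub.params["merit"] if len(sub) else 0.0
            agree += abs(max(merit, 0.0) - max(best, 0.0)) < 1e-9
        assert agree == 20

    def test_covers_distinct_informative_signals(self):
        spec = SyntheticSpec(
            n_pos=40, n_neg=40, n_informative_shift=3, shift_effect=2.0,
            n_informative_scale=0, n_redundant=3, redundancy_noise=0.05,
            n_noise=50, seed=4,
        )
        ds, truth = generate_synthetic(spec)
        z = zscore_standardize(ds)
        sub = cfs_select(z, z.gene_ids)
        source = dict(zip(truth.gene_id, truth.source))
        roles = dict(zip(truth.gene_id, truth.role))
        signals = {
            source[g] if roles[g] == "redundant" else g
            for g in sub.gene_ids
            if roles[g] != "noise"
        }
        assert len(signals) >= 2

    def test_exact_duplicates_not_doubled(self):
        """With exact copies and precise association estimates, the merit
        penalizes keeping both members of a duplicate pair."""
        spec = SyntheticSpec(
            n_pos=150, n_neg=150, n_informative_shift=12, shift_effect=1.5,
            n_informative_scale=0, n_redundant=3, redundancy_noise=0.0,
            n_noise=50, seed=0,
        )
        ds, truth = generate_synthetic(spec)
        z = zscore_standardize(ds)
        sub = set(cfs_select(z, z.gene_ids).gene_ids)
        pairs = [(r.source, r.gene_id) for r in truth.itertuples() if r.role == "redundant"]
        assert all(not (a in sub and b in sub) for a, b in pairs)

    def test_all_constant_candidates_yield_empty_selection(self):
        ds = make_dataset(np.ones((8, 3)), [1, 1, 1, 1, 0, 0, 0, 0])
        with pytest.warns(UserWarning, match="class information"):
            sub = cfs_select(ds, ds.gene_ids)
        assert len(sub) == 0

    def test_result_within_parent(self, small_informative):
        ds, _ = small_informative
        candidates = filter_genes(ds, "ks", 0.01).selected
        sub = cfs_select(ds, candidates)
        assert set(sub.gene_ids) <= set(candidates.gene_ids)
        assert sub.parent is candidates


def greedy_mid_oracle(disc, labels, k):
    """Independent reimplementation of the greedy MID recursion."""
    n = len(disc)
    rel = [contingency_mi_bits(d, labels) for d in disc]
    picked, remaining = [], list(range(n))
    while remaining and len(picked) < k:
        if not picked:
            scores = {g: rel[g] for g in remaining}
        else:
            scores = {
                g: rel[g] - np.mean([contingency_mi_bits(disc[g], disc[s]) for s in picked])
                for g in remaining
            }
        g = min(remaining, key=lambda g: (-scores[g], g))
        picked.append(g)
        remaining.remove(g)
    return picked


class TestMRMR:
    def test_first_pick_maximizes_relevance(self, small_informative):
        ds, _ = small_informative
        from kscfs.discretize import three_level_discretize

        ranked = mrmr_rank(ds, ds.gene_ids, k=5)
        rel = {
            g: mutual_information(three_level_discretize(ds.gene_column(g)), ds.labels)
            for g in ds.gene_ids
        }
        assert rel[ranked.gene_ids[0]] == pytest.approx(max(rel.values()))

    def test_matches_greedy_oracle_on_12_candidates(self):
        from kscfs.discretize import three_level_discretize

        rng = np.random.default_rng(7)
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        vals = rng.standard_normal((60, 12))
        vals[:, :4] += y[:, None] * rng.uniform(0.5, 1.5, size=4)
        ds = make_dataset(vals, y)
        ranked = mrmr_rank(ds, ds.gene_ids, k=12)
        disc = [three_level_discretize(ds.values[:, j]) for j in range(12)]
        expected = greedy_mid_oracle(disc, ds.labels, 12)
        assert list(ranked.gene_ids) == [f"g{j}" for j in expected]

    def test_duplicate_ranks_below_independent_relevant_gene(self):
        rng = np.random.default_rng(9)
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        top = y * 2.0 + rng.standard_normal(100) * 0.5
        dup = top + rng.standard_normal(100) * 0.05
        indep = y * 1.0 + rng.standard_normal(100) * 0.8
        noise = rng.standard_normal((100, 5))
        ds = make_dataset(np.column_stack([top, dup, indep, noise]), y)
        ranked = mrmr_rank(ds, ds.gene_ids, k=3)
        assert ranked.gene_ids[0] == "g0"
        order = {g: i for i, g in enumerate(ranked.gene_ids)}
        assert order["g2"] < order.get("g1", 99)

    def test_scores_nonincreasing(self, small_informative):
        ds, _ = small_informative
        ranked = mrmr_rank(ds, ds.gene_ids, k=20)
        assert all(a >= b for a, b in zip(ranked.scores, ranked.scores[1:]))


def relieff_oracle(x, y, k):
    """Brute-force ReliefF on a tiny matrix, all instances, k neighbors."""
    n, p = x.shape
    rng_range = x.max(axis=0) - x.min(axis=0)
    rng_range[rng_range == 0] = 1.0
    w = np.zeros(p)
    for i in range(n):
        diffs = np.abs(x - x[i]) / rng_range
        dist = diffs.sum(axis=1)
        same = [j for j in range(n) if y[j] == y[i] and j != i]
        opp = [j for j in range(n) if y[j] != y[i]]
        hits = sorted(same, key=lambda j: dist[j])[:k]
        misses = sorted(opp, key=lambda j: dist[j])[:k]
        w -= np.mean([diffs[j] for j in hits], axis=0)
        w += np.mean([diffs[j] for j in misses], axis=0)
    return w / n


class TestReliefF:
    def test_constant_gene_zero_weight(self):
        rng = np.random.default_rng(1)
        vals = np.c_[np.full(12, 2.0), rng.standard_normal((12, 2))]
        ds = make_dataset(vals, [1] * 6 + [0] * 6)
        w = relieff_weights(ds, ds.gene_ids, k_neighbors=2)
        assert w[0] == 0.0

    def test_matches_brute_force_oracle_on_toy(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((6, 3))
        y = np.array([1, 1, 1, 0, 0, 0])
        ds = make_dataset(x, y)
        w = relieff_weights(ds, ds.gene_ids, k_neighbors=2)
        np.testing.assert_allclose(w, relieff_oracle(x, y, 2), atol=1e-12)

    def test_shift_genes_outrank_all_noise(self):
        spec = SyntheticSpec(
            n_pos=50, n_neg=50, n_informative_shift=5, shift_effect=2.0,
            n_informative_scale=0, n_redundant=0, n_noise=40, seed=3,
        )
        ds, truth = generate_synthetic(spec)
        z = zscore_standardize(ds)
        ranked = relieff_rank(z, z.gene_ids, k_neighbors=10, k=45)
        shift = set(truth[truth.role == "shift"].gene_id)
        assert set(ranked.gene_ids[:5]) == shift

    def test_k_neighbors_must_fit_class_size(self):
        ds = make_dataset(np.random.default_rng(0).standard_normal((8, 2)), [1] * 4 + [0] * 4)
        with pytest.raises(ValueError, match="k_neighbors"):
            relieff_weights(ds, ds.gene_ids, k_neighbors=4)


class TestForwardSelect:
    def test_transparent_evaluator_recovers_target_set(self):
        target = {"g1", "g3"}
        ranked = RankedGenes(("g1", "g3", "g2", "g4"), (4.0, 3.0, 2.0, 1.0))
        evaluator = lambda ids: len(set(ids) & target) / len(target)
        sub = forward_select(ranked, evaluator)
        assert set(sub.gene_ids) == target

    def test_constant_evaluator_keeps_first_gene_only(self):
        ranked = RankedGenes(("a", "b", "c"), (3.0, 2.0, 1.0))
        sub = forward_select(ranked, lambda ids: 0.5)
        assert sub.gene_ids == ("a",)

    def test_score_recorded(self):
        ranked = RankedGenes(("a", "b"), (1.0, 0.5))
        sub = forward_select(ranked, lambda ids: float(len(ids)))
        assert sub.gene_ids == ("a", "b")
        assert sub.params["score"] == 2.0


class TestRankingInvariants:
    def test_ranking_invariant_to_candidate_order(self, small_informative):
        ds, _ = small_informative
        ids = list(ds.gene_ids[:20])
        reversed_ids = ids[::-1]
        r1 = mrmr_rank(ds, ids, k=10)
        r2 = mrmr_rank(ds, reversed_ids, k=10)
        assert set(r1.gene_ids) == set(r2.gene_ids)
        r3 = relieff_rank(ds, ids, k_neighbors=5, k=10)
        r4 = relieff_rank(ds, reversed_ids, k_neighbors=5, k=10)
        assert r3.gene_ids == r4.gene_ids

    def test_subset_provenance_validation(self):
        parent = GeneSubset(("a", "b"), method="parent")
        with pytest.raises(ValueError, match="not in parent"):
            GeneSubset(("c",), parent=parent)
        with pytest.raises(ValueError, match="duplicate"):
            GeneSubset(("a", "a"))
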
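"""Multivariate gene selection: CFS, mRMR, ReliefF and wrapper forward selection.

Correlation-based feature selection (CFS) scores a candidate subset S of k
genes by the merit

    merit(S) = k * mean(r_cf) / sqrt(k + k (k - 1) * mean(r_ff)),

where r_cf is the gene-class association and r_ff the gene-gene association,
both measured as symmetrical uncertainty SU(a, b) = 2 I(a; b) / (H(a) + H(b))
over MDL-discretized expression values. The merit rewards subsets whose
members predict the class (high r_cf) while penalizing mutual redundancy
(high r_ff); a best-first search over the subset lattice maximizes it.

mRMR ranks genes greedily by mutual-information relevance minus mean
redundancy against the genes already picked (the MID "difference" form);
ReliefF weights genes by how well they separate nearest neighbors of
opposite classes versus same-class neighbors. Both produce a ranked list
from which a wrapper (``forward_select``) grows a subset guided by a
classifier-accuracy evaluator.
"""

from __future__ import annotations

import heapq
import warnings
from typing import Callable, Literal, Sequence

import numpy as np

from .datasets import ExpressionDataset
from .discretize import equal_frequency_discretize, mdl_discretize, three_level_discretize
from .selection_types import GeneSubset, RankedGenes

__all__ = [
    "symmetric_uncertainty",
    "mutual_information",
    "CorrelationCache",
    "cfs_merit",
    "cfs_select",
    "mrmr_rank",
    "relieff_rank",
    "forward_select",
]


def _codes(x: np.ndarray) -> np.ndarray:
    return np.unique(np.asarray(x), return_inverse=True)[1]


def _entropies(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(H(a), H(b), H(a,b)) in bits for discrete code vectors."""
    a = _codes(a)
    b = _codes(b)
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float)
    n = joint.sum()
    p = joint[joint > 0] / n
    h_ab = float(-(p * np.log2(p)).sum())
    pa = np.bincount(a).astype(float) / n
    pb = np.bincount(b).astype(float) / n
    h_a = float(-(pa[pa > 0] * np.log2(pa[pa > 0])).sum())
    h_b = float(-(pb[pb > 0] * np.log2(pb[pb > 0])).sum())
    return h_a, h_b, h_ab


def mutual_information(a: Sequence, b: Sequence) -> float:
    """I(a; b) in bits over discrete sequences."""
    h_a, h_b, h_ab = _entropies(np.asarray(a), np.asarray(b))
    return max(0.0, h_a + h_b - h_ab)


def symmetric_uncertainty(
    a: Sequence, b: Sequence, discretizer: Literal["none", "ef"] = "none", bins: int = 10
) -> float:
    """SU(a, b) = 2 I(a; b) / (H(a) + H(b)), in [0, 1].

    Inputs are treated as categorical (``discretizer="none"``) or first cut
    into equal-frequency bins (``"ef"``). A constant sequence has zero
    entropy and SU is defined as 0. Class-supervised MDL discretization is
    applied upstream (see :class:`CorrelationCache`), not here, because it
    needs the class labels.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("sequences must have equal length >= 2")
    if discretizer == "ef":
        a = equal_frequency_discretize(a.astype(float), bins)
        b = equal_frequency_discretize(b.astype(float), bins)
    h_a, h_b, h_ab = _entropies(a, b)
    if h_a == 0.0 or h_b == 0.0:
        return 0.0
    i_ab = max(0.0, h_a + h_b - h_ab)
    return float(np.clip(2.0 * i_ab / (h_a + h_b), 0.0, 1.0))


class CorrelationCache:
    """Gene-class and gene-gene symmetrical uncertainties, computed lazily.

    Every candidate gene is discretized once (MDL against the class by
    default, or equal-frequency); SU values are then computed over the
    discrete codes on demand and memoized. Gene-gene SU is symmetric and the
    diagonal is 1 for any gene that survived discretization with >= 2 bins.
    """

    def __init__(
        self,
        ds: ExpressionDataset,
        gene_ids: Sequence[str],
        discretizer: Literal["mdl", "ef"] = "mdl",
        bins: int = 10,
    ):
        self.gene_ids = tuple(gene_ids)
        self.labels = ds.labels
        self._disc = []
        for g in self.gene_ids:
            col = ds.gene_column(g)
            if discretizer == "mdl":
                self._disc.append(mdl_discretize(col, ds.labels))
            else:
                self._disc.append(equal_frequency_discretize(col, bins))
        self.feature_class = np.array(
            [
                0.0 if d.max() == d.min() else symmetric_uncertainty(d, ds.labels)
                for d in self._disc
            ]
        )
        self._ff: dict[tuple[int, int], float] = {}

    def __len__(self) -> int:
        return len(self.gene_ids)

    def feature_feature(self, i: int, j: int) -> float:
        if i == j:
            return 1.0 if self._disc[i].max() > self._disc[i].min() else 0.0
        key = (i, j) if i < j else (j, i)
        if key not in self._ff:
            self._ff[key] = symmetric_uncertainty(self._disc[key[0]], self._disc[key[1]])
        return self._ff[key]


def cfs_merit(subset: Sequence[int], cache: CorrelationCache) -> float:
    """CFS merit of a subset given by candidate indices; empty subset -> 0."""
    k = len(subset)
    if k == 0:
        return 0.0
    sum_rcf = float(cache.feature_class[list(subset)].sum())
    if k == 1:
        return sum_rcf
    sum_rff = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            sum_rff += cache.feature_feature(subset[a], subset[b])
    mean_rcf = sum_rcf / k
    mean_rff = 2.0 * sum_rff / (k * (k - 1))
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def cfs_select(
    ds: ExpressionDataset,
    candidates: GeneSubset | Sequence[str],
    discretizer: Literal["mdl", "ef"] = "mdl",
    stall_limit: int = 5,
    cache: CorrelationCache | None = None,
) -> GeneSubset:
    """Best-first search over subsets of ``candidates`` maximizing CFS merit.

    Forward best-first: starting from the empty set, the open list holds
    evaluated nodes keyed by merit; the best unexpanded node is expanded by
    single-gene additions. The search stops after ``stall_limit`` consecutive
    expansions that fail to improve the best merit found. Ties break toward
    the subset discovered first (and genes in original column order), making
    the search deterministic.
    """
    parent = (
        candidates
        if isinstance(candidates, GeneSubset)
        else GeneSubset(tuple(candidates), method="candidates")
    )
    if len(parent) == 0:
        raise ValueError("candidate set is empty")
    if cache is None:
        cache = CorrelationCache(ds, parent.gene_ids, discretizer=discretizer)
    n = len(cache)
    if np.all(cache.feature_class == 0.0):
        warnings.warn("no candidate gene carries class information; empty selection")
        return GeneSubset(
            (), method="cfs", params={"discretizer": discretizer, "merit": 0.0}, parent=parent
        )

    # node = frozenset of candidate indices; carry (sum_rcf, sum_rff) for
    # O(k) incremental merit evaluation of children
    counter = 0
    heap: list[tuple[float, int, frozenset, float, float]] = []
    visited: set[frozenset] = set()

    def push(node: frozenset, merit: float, s_rcf: float, s_rff: float) -> None:
        nonlocal counter
        counter += 1
        heapq.heappush(heap, (-merit, counter, node, s_rcf, s_rff))

    empty = frozenset()
    push(empty, 0.0, 0.0, 0.0)
    visited.add(empty)
    best_merit = -1.0
    best_node = empty
    stalls = 0

    while heap and stalls < stall_limit:
        _, _, node, s_rcf, s_rff = heapq.heappop(heap)
        improved = False
        for g in range(n):
            if g in node:
                continue
            child = node | {g}
            if child in visited:
                continue
            visited.add(child)
            c_rcf = s_rcf + float(cache.feature_class[g])
            c_rff = s_rff + sum(cache.feature_feature(g, h) for h in node)
            k = len(child)
            if k == 1:
                merit = c_rcf
            else:
                mean_rff = 2.0 * c_rff / (k * (k - 1))
                merit = c_rcf / np.sqrt(k + k * (k - 1) * mean_rff)
            push(child, merit, c_rcf, c_rff)
            if merit > best_merit + 1e-12:
                best_merit = merit
                best_node = child
                improved = True
        stalls = 0 if improved else stalls + 1

    ordered = tuple(g for i, g in enumerate(cache.gene_ids) if i in best_node)
    return GeneSubset(
        gene_ids=ordered,
        method="cfs",
        params={"discretizer": discretizer, "stall_limit": stall_limit, "merit": best_merit},
        parent=parent,
    )


def mrmr_rank(
    ds: ExpressionDataset,
    candidates: GeneSubset | Sequence[str],
    k: int = 50,
    variant: Literal["mid", "miq"] = "mid",
) -> RankedGenes:
    """Greedy minimum-redundancy maximum-relevance ranking.

    Genes are 3-level discretized (mean ± sd); the first pick maximizes
    I(gene; class) and each later pick maximizes relevance minus mean
    redundancy against the picked set (MID) or relevance over redundancy
    (MIQ). Reported scores are the running minimum of the incremental
    objective so they form a nonincreasing ranking weight; the rank order
    itself is the raw greedy order.
    """
    ids = tuple(candidates) if not isinstance(candidates, GeneSubset) else candidates.gene_ids
    if len(ids) == 0:
        raise ValueError("candidate set is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    # ties break on original dataset column order, independent of candidate order
    col = {g: ds.gene_index(g) for g in ids}
    disc = [three_level_discretize(ds.gene_column(g)) for g in ids]
    rel = np.array([mutual_information(d, ds.labels) for d in disc])
    n = len(ids)
    picked: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(n)
    remaining = set(range(n))
    while remaining and len(picked) < min(k, n):
        if not picked:
            obj = {g: rel[g] for g in remaining}
        elif variant == "mid":
            obj = {g: rel[g] - red_sum[g] / len(picked) for g in remaining}
        else:
            obj = {g: rel[g] / max(red_sum[g] / len(picked), 1e-12) for g in remaining}
        g_best = min(remaining, key=lambda g: (-obj[g], col[ids[g]]))
        picked.append(g_best)
        scores.append(obj[g_best])
        remaining.discard(g_best)
        for g in remaining:
            red_sum[g] += mutual_information(disc[g], disc[g_best])
    mono = np.minimum.accumulate(scores)
    return RankedGenes(
        gene_ids=tuple(ids[g] for g in picked),
        scores=tuple(mono),
        method="mrmr",
        params={"variant": variant, "k": k},
    )


def relieff_weights(
    ds: ExpressionDataset,
    gene_ids: Sequence[str],
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """ReliefF feature weights over the given genes.

    For each sampled instance the weight of a gene drops by its mean
    range-normalized distance to the ``k_neighbors`` nearest same-class hits
    and rises by the class-prior-weighted mean distance to the nearest
    opposite-class misses; distances between instances are Manhattan over
    range-normalized values. With ``n_iterations=None`` every instance is
    used once (deterministic); otherwise instances are sampled without
    replacement with the given seed.
    """
    idx = [ds.gene_index(g) for g in gene_ids]
    x = ds.values[:, idx]
    y = ds.labels
    n, p = x.shape
    counts = np.bincount(y, minlength=2)
    if k_neighbors >= counts.min():
        raise ValueError(
            f"k_neighbors={k_neighbors} must be < the smaller class size {counts.min()}"
        )
    rng_range = x.max(axis=0) - x.min(axis=0)
    rng_range[rng_range == 0] = 1.0  # constant gene: all diffs are 0 anyway
    diffs = np.abs(x[:, None, :] - x[None, :, :]) / rng_range  # (n, n, p)
    dist = diffs.sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    priors = counts / n

    if n_iterations is None or n_iterations >= n:
        instances = np.arange(n)
    else:
        instances = np.sort(
            np.random.default_rng(seed).choice(n, size=n_iterations, replace=False)
        )
    w = np.zeros(p)
    for i in instances:
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        opp = np.flatnonzero(y != y[i])
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_neighbors]]
        misses = opp[np.argsort(dist[i, opp], kind="stable")[:k_neighbors]]
        opp_prior = priors[1 - y[i]] / (1 - priors[y[i]])  # = 1 for two classes
        w -= diffs[i, hits].mean(axis=0)
        w += opp_prior * diffs[i, misses].mean(axis=0)
    return w / len(instances)


def relieff_rank(
    ds: ExpressionDataset,
    candidates: GeneSubset | Sequence[str],
    k_neighbors: int = 10,
    n_iterations: int | None = None,
    k: int = 50,
    seed: int = 0,
) -> RankedGenes:
    """Top-``k`` genes by ReliefF weight (ties to original column order)."""
    ids = tuple(candidates) if not isinstance(candidates, GeneSubset) else candidates.gene_ids
    if len(ids) == 0:
        raise ValueError("candidate set is empty")
    w = relieff_weights(ds, ids, k_neighbors=k_neighbors, n_iterations=n_iterations, seed=seed)
    col = {g: ds.gene_index(g) for g in ids}
    order = sorted(range(len(ids)), key=lambda i: (-w[i], col[ids[i]]))[: min(k, len(ids))]
    return RankedGenes(
        gene_ids=tuple(ids[i] for i in order),
        scores=tuple(w[i] for i in order),
        method="relieff",
        params={"k_neighbors": k_neighbors, "k": k},
    )


def forward_select(
    ranked: RankedGenes,
    evaluator: Callable[[Sequence[str]], float],
) -> GeneSubset:
    """Grow a subset along a ranked list, keeping strict improvements only.

    The top-ranked gene seeds the subset; each subsequent gene is kept iff
    adding it strictly increases the evaluator's score (typically a
    cross-validated accuracy). Strictness prevents unbounded growth under
    ties. The final score is stored in ``params["score"]``.
    """
    if len(ranked) == 0:
        raise ValueError("ranked list is empty")
    selected = [ranked.gene_ids[0]]
    best = evaluator(tuple(selected))
    for g in ranked.gene_ids[1:]:
        trial = evaluator(tuple(selected) + (g,))
        if trial > best:
            selected.append(g)
            best = trial
    return GeneSubset(
        gene_ids=tuple(selected),
        method=f"{ranked.method}+forward" if ranked.method else "forward",
        params={"score": best, **ranked.params},
    )
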
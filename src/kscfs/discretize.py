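"""Supervised and unsupervised discretization of expression values.

Association measures built on entropy need discrete inputs. Three schemes are
provided, matching the conventions the selectors expect:

* ``mdl_discretize`` — recursive entropy-based partitioning with the minimum
  description length (MDL) stopping criterion. Class-supervised; a gene for
  which no cut passes the MDL test collapses to a single bin and is thereby
  declared irrelevant (its class association becomes 0).
* ``equal_frequency_discretize`` — unsupervised fallback, default 10 bins.
* ``three_level_discretize`` — low/medium/high coding with thresholds at
  mean ± one standard deviation, the usual preprocessing for
  mutual-information gene ranking.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "mdl_cut_points",
    "mdl_discretize",
    "equal_frequency_discretize",
    "three_level_discretize",
]


def _entropy_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def mdl_cut_points(values, labels) -> list[float]:
    """Cut points chosen by recursive entropy minimization with MDL stopping.

    Candidate cuts are midpoints between adjacent distinct sorted values; the
    cut minimizing the class-weighted entropy is accepted only if its
    information gain exceeds the MDL cost ``(log2(N-1) + Δ)/N``, then each
    side is partitioned recursively. Returns an ascending (possibly empty)
    list of thresholds.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    v = values[order]
    classes, y = np.unique(labels[order], return_inverse=True)
    k_all = len(classes)
    # prefix[i, c] = count of class c among the first i sorted samples
    prefix = np.zeros((len(v) + 1, k_all), dtype=np.int64)
    onehot = np.zeros((len(v), k_all), dtype=np.int64)
    onehot[np.arange(len(v)), y] = 1
    prefix[1:] = np.cumsum(onehot, axis=0)

    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg = prefix[hi] - prefix[lo]
        e_s = _entropy_counts(seg)
        if e_s == 0.0:
            return
        # candidate boundaries: i in (lo, hi) with v[i-1] != v[i]
        idx = np.arange(lo + 1, hi)
        idx = idx[v[idx - 1] != v[idx]]
        if idx.size == 0:
            return
        left = prefix[idx] - prefix[lo]
        right = seg - left
        n_left = left.sum(axis=1)
        n_right = n - n_left
        with np.errstate(divide="ignore", invalid="ignore"):
            def ent(block, sizes):
                p = block / sizes[:, None]
                t = np.where(block > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
                return t.sum(axis=1)

            e_left = ent(left, n_left)
            e_right = ent(right, n_right)
        weighted = (n_left * e_left + n_right * e_right) / n
        best = int(np.argmin(weighted))
        gain = e_s - weighted[best]
        k = int((seg > 0).sum())
        k1 = int((left[best] > 0).sum())
        k2 = int((right[best] > 0).sum())
        delta = math.log2(3**k - 2) - (k * e_s - k1 * e_left[best] - k2 * e_right[best])
        if gain <= (math.log2(n - 1) + delta) / n:
            return
        cut_at = int(idx[best])
        cuts.append((v[cut_at - 1] + v[cut_at]) / 2.0)
        recurse(lo, cut_at)
        recurse(cut_at, hi)

    recurse(0, len(v))
    return sorted(cuts)


def mdl_discretize(values, labels) -> np.ndarray:
    """Integer bin codes from :func:`mdl_cut_points` (0 bins cuts = all-zero)."""
    cuts = mdl_cut_points(values, labels)
    return np.searchsorted(np.asarray(cuts), np.asarray(values, dtype=float), side="right")


def equal_frequency_discretize(values, bins: int = 10) -> np.ndarray:
    """Equal-frequency binning into at most ``bins`` bins (ties merged)."""
    values = np.asarray(values, dtype=float)
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    cuts = np.unique(qs)
    return np.searchsorted(cuts, values, side="right")


def three_level_discretize(values) -> np.ndarray:
    """Code each value as 0 (< mean - sd), 1, or 2 (> mean + sd)."""
    values = np.asarray(values, dtype=float)
    mu = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if sd == 0:
        return np.zeros(values.shape, dtype=int)
    codes = np.ones(values.shape, dtype=int)
    codes[values < mu - sd] = 0
    codes[values > mu + sd] = 2
    return codes
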
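"""Cross-validated linear-SVM accuracy of gene subsets.

The classifier is deliberately an off-the-shelf component: a support vector
machine with a linear kernel and penalty C = 1, never tuned. Accuracies are
percentages of correctly classified held-out samples under seeded stratified
k-fold splits. ``repeated_shuffle_evaluation`` implements the
shuffle-select-evaluate protocol: the sample order is reshuffled per repeat,
the selector is re-run on the shuffled data, and the selected subset is
cross-validated; means over all repeats x folds are reported together with
the mean selected-gene count.

By default selection runs once per repeat on the full (shuffled) dataset and
the same subset is used in every fold — the conventional protocol in the
gene-selection literature, which carries a known selection bias. A stricter
mode (``select_per_fold=True``) re-runs the selector inside each training
fold and is the methodologically cleaner estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import ExpressionDataset
from .selection_types import GeneSubset

__all__ = ["EvaluationResult", "svm_cv_accuracy", "repeated_shuffle_evaluation", "make_svm_evaluator"]

Selector = Callable[[ExpressionDataset], GeneSubset]


@dataclass(frozen=True)
class EvaluationResult:
    """Per-(repeat, fold) accuracies (percent) with summary statistics."""

    accuracies: tuple[float, ...]
    folds: int
    repeats: int
    seed: int
    n_genes: float  # mean selected-gene count over successful repeats
    failed_repeats: tuple[int, ...] = ()
    mean_accuracy: float = field(init=False)

    def __post_init__(self):
        accs = np.asarray(self.accuracies, dtype=float)
        if accs.size and (accs.min() < 0 or accs.max() > 100):
            raise ValueError("accuracies must lie in [0, 100]")
        object.__setattr__(
            self, "mean_accuracy", float(accs.mean()) if accs.size else float("nan")
        )

    def to_tsv(self, path: str | Path) -> None:
        lines = ["repeat\tfold\taccuracy"]
        i = 0
        for r in range(self.repeats):
            if r in self.failed_repeats:
                continue
            for f in range(self.folds):
                lines.append(f"{r}\t{f}\t{self.accuracies[i]:.6g}")
                i += 1
        Path(path).write_text("\n".join(lines) + "\n")
        summary = {
            "mean_accuracy": self.mean_accuracy,
            "n_genes": self.n_genes,
            "folds": self.folds,
            "repeats": self.repeats,
            "seed": self.seed,
            "failed_repeats": list(self.failed_repeats),
        }
        Path(path).with_suffix(".summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )


def _linear_svm() -> SVC:
    return SVC(kernel="linear", C=1.0)


def _effective_folds(ds: ExpressionDataset, folds: int) -> int:
    smallest = min(ds.n_pos, ds.n_neg)
    if smallest < folds:
        warnings.warn(
            f"reducing folds from {folds} to {smallest}: smallest class has "
            f"only {smallest} samples"
        )
        return max(2, smallest)
    return folds


def svm_cv_accuracy(
    ds: ExpressionDataset,
    subset: GeneSubset | Sequence[str],
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Stratified k-fold accuracies (%) of a linear SVM (C=1) on a subset.

    Deterministic in (dataset, subset, folds, seed).
    """
    ids = tuple(subset) if not isinstance(subset, GeneSubset) else subset.gene_ids
    if len(ids) == 0:
        raise ValueError("cannot evaluate an empty gene subset")
    x = ds.restrict_genes(ids).values
    y = ds.labels
    folds = _effective_folds(ds, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(x, y):
        clf = _linear_svm().fit(x[train], y[train])
        accs.append(100.0 * float((clf.predict(x[test]) == y[test]).mean()))
    return np.asarray(accs)


def make_svm_evaluator(
    ds: ExpressionDataset, folds: int = 10, seed: int = 0
) -> Callable[[Sequence[str]], float]:
    """Mean CV accuracy as a subset -> score contract for wrapper selection."""

    def evaluate(gene_ids: Sequence[str]) -> float:
        return float(svm_cv_accuracy(ds, tuple(gene_ids), folds=folds, seed=seed).mean())

    return evaluate


def repeated_shuffle_evaluation(
    ds: ExpressionDataset,
    selector: Selector,
    folds: int = 10,
    repeats: int = 10,
    base_seed: int = 0,
    select_per_fold: bool = False,
) -> EvaluationResult:
    """Shuffle, select, cross-validate; average over repeats.

    For repeat r the sample order is permuted with seed ``base_seed + r``,
    the selector is applied, and its subset is evaluated by
    :func:`svm_cv_accuracy` with the same seed. A repeat whose selector
    returns an empty subset is recorded as failed and excluded from the
    means. Identical inputs and ``base_seed`` give identical results.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    all_accs: list[float] = []
    gene_counts: list[int] = []
    failed: list[int] = []
    eff_folds = _effective_folds(ds, folds)
    for r in range(repeats):
        seed_r = base_seed + r
        shuffled = ds.shuffled(seed_r)
        if select_per_fold:
            skf = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed_r)
            x, y = shuffled.values, shuffled.labels
            fold_accs, fold_counts = [], []
            for train, test in skf.split(x, y):
                train_ds = ExpressionDataset(
                    values=x[train],
                    labels=y[train],
                    gene_ids=shuffled.gene_ids,
                    sample_ids=tuple(shuffled.sample_ids[i] for i in train),
                    label_names=shuffled.label_names,
                )
                sub = selector(train_ds)
                if len(sub) == 0:
                    continue
                cols = [shuffled.gene_index(g) for g in sub.gene_ids]
                clf = _linear_svm().fit(x[train][:, cols], y[train])
                fold_accs.append(100.0 * float((clf.predict(x[test][:, cols]) == y[test]).mean()))
                fold_counts.append(len(sub))
            if not fold_accs:
                warnings.warn(f"repeat {r}: selector returned empty subsets; repeat skipped")
                failed.append(r)
                continue
            all_accs.extend(fold_accs)
            gene_counts.append(int(np.mean(fold_counts)))
        else:
            sub = selector(shuffled)
            if len(sub) == 0:
                warnings.warn(f"repeat {r}: selector returned an empty subset; repeat skipped")
                failed.append(r)
                continue
            all_accs.extend(svm_cv_accuracy(shuffled, sub, folds=folds, seed=seed_r).tolist())
            gene_counts.append(len(sub))
    return EvaluationResult(
        accuracies=tuple(all_accs),
        folds=eff_folds,
        repeats=repeats,
        seed=base_seed,
        n_genes=float(np.mean(gene_counts)) if gene_counts else float("nan"),
        failed_repeats=tuple(failed),
    )
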
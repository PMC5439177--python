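"""The two-stage K-S/CFS gene-selection pipeline and comparison runners.

Stage 1 screens every gene with the two-sample Kolmogorov-Smirnov test at a
significance level α (default 0.01), discarding genes whose class
distributions are indistinguishable; stage 2 runs correlation-based feature
selection over the surviving candidates to strip redundancy and return a
compact subset. The screen makes CFS tractable on matrices with tens of
thousands of genes, and the CFS stage removes the mutually redundant genes a
univariate filter necessarily keeps.

Two runners reproduce the standard comparison protocols: an α-sweep of the
univariate filters (selected-gene counts and CV accuracies across
significance levels) and a five-way method comparison (K-S+CFS, CFS alone,
K-S alone, mRMR and ReliefF with top-k ranking plus wrapper forward
selection) under the repeated-shuffle evaluation protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .datasets import ExpressionDataset
from .evaluation import (
    EvaluationResult,
    make_svm_evaluator,
    repeated_shuffle_evaluation,
    svm_cv_accuracy,
)
from .selection_types import GeneSubset
from .selectors import cfs_select, forward_select, mrmr_rank, relieff_rank
from .univariate import filter_genes

__all__ = [
    "PipelineConfig",
    "ComparisonReport",
    "ks_cfs_select",
    "make_selector",
    "run_alpha_sweep",
    "run_method_comparison",
]

MethodName = Literal["ks_cfs", "cfs", "ks", "mrmr", "relieff"]
METHODS: tuple[str, ...] = ("ks_cfs", "cfs", "ks", "mrmr", "relieff")


@dataclass(frozen=True)
class PipelineConfig:
    """Protocol parameters; defaults reproduce the standard study protocol
    (α = 0.01 prescreen, top-50 ranked lists, 10 folds x 10 repeats)."""

    alpha: float = 0.01
    stage1_test: Literal["ks", "wilcoxon", "t"] = "ks"
    stage2: Literal["cfs", "mrmr+forward", "relieff+forward", "none"] = "cfs"
    top_k: int = 50
    folds: int = 10
    repeats: int = 10
    base_seed: int = 0
    prescreen_baselines: bool = False  # run CFS/mRMR/ReliefF rows on the K-S prescreen
    relieff_k_neighbors: int = 10

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass(frozen=True)
class ComparisonReport:
    """Tabular results: one row per (method, α) with gene count and accuracy."""

    rows: pd.DataFrame
    config: PipelineConfig = field(default_factory=PipelineConfig)
    details: dict = field(default_factory=dict, compare=False)

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def ks_cfs_select(
    ds: ExpressionDataset,
    alpha: float = 0.01,
    discretizer: Literal["mdl", "ef"] = "mdl",
    stall_limit: int = 5,
) -> GeneSubset:
    """Two-stage selection: K-S filter at α, then CFS over the candidates.

    The result's ``parent`` is the stage-1 candidate subset, so the
    containment chain (final ⊆ candidates ⊆ all genes) is explicit. An empty
    stage-1 set returns an empty subset carrying a diagnostic.
    """
    report = filter_genes(ds, "ks", alpha)
    candidates = report.selected
    if len(candidates) == 0:
        warnings.warn(f"K-S stage selected no genes at alpha={alpha}")
        return GeneSubset(
            (), method="ks_cfs", params={"alpha": alpha, "diagnostic": f"empty K-S stage at alpha={alpha}"}
        )
    sub = cfs_select(ds, candidates, discretizer=discretizer, stall_limit=stall_limit)
    return GeneSubset(
        gene_ids=sub.gene_ids,
        method="ks_cfs",
        params={"alpha": alpha, **sub.params},
        parent=candidates,
    )


def make_selector(method: str, config: PipelineConfig):
    """Build a dataset -> GeneSubset selector for one comparison method."""

    def stage1(ds: ExpressionDataset) -> GeneSubset:
        return filter_genes(ds, "ks", config.alpha).selected

    def candidate_pool(ds: ExpressionDataset) -> GeneSubset:
        if config.prescreen_baselines:
            return stage1(ds)
        return GeneSubset(ds.gene_ids, method="all_genes")

    if method == "ks_cfs":
        return lambda ds: ks_cfs_select(ds, alpha=config.alpha)
    if method == "ks":
        return stage1
    if method == "cfs":
        return lambda ds: cfs_select(ds, candidate_pool(ds))
    if method == "mrmr":

        def select_mrmr(ds: ExpressionDataset) -> GeneSubset:
            pool = candidate_pool(ds)
            if len(pool) == 0:
                return GeneSubset((), method="mrmr+forward")
            ranked = mrmr_rank(ds, pool, k=config.top_k)
            return forward_select(
                ranked, make_svm_evaluator(ds, folds=config.folds, seed=config.base_seed)
            )

        return select_mrmr
    if method == "relieff":

        def select_relieff(ds: ExpressionDataset) -> GeneSubset:
            pool = candidate_pool(ds)
            if len(pool) == 0:
                return GeneSubset((), method="relieff+forward")
            ranked = relieff_rank(
                ds, pool, k_neighbors=config.relieff_k_neighbors, k=config.top_k
            )
            return forward_select(
                ranked, make_svm_evaluator(ds, folds=config.folds, seed=config.base_seed)
            )

        return select_relieff
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def run_alpha_sweep(
    ds: ExpressionDataset,
    tests: Sequence[str] = ("ks", "wilcoxon", "t"),
    alphas: Sequence[float] = (1.0, 0.05, 0.01, 0.005, 0.001),
    config: PipelineConfig = PipelineConfig(),
) -> ComparisonReport:
    """Selected-gene counts and CV accuracies per (test, α).

    For each univariate test and level the filter is applied once and the
    selected subset cross-validated; counts are nonincreasing as α shrinks
    because the selections are nested.
    """
    if not alphas:
        raise ValueError("alphas must be nonempty")
    rows = []
    for test in tests:
        for alpha in alphas:
            selected = filter_genes(ds, test, alpha).selected
            if len(selected) == 0:
                acc = float("nan")
            else:
                acc = float(
                    svm_cv_accuracy(
                        ds, selected, folds=config.folds, seed=config.base_seed
                    ).mean()
                )
            rows.append(
                {"test": test, "alpha": alpha, "n_genes": len(selected), "accuracy": acc}
            )
    return ComparisonReport(rows=pd.DataFrame(rows), config=config)


def run_method_comparison(
    ds: ExpressionDataset,
    methods: Sequence[str] = METHODS,
    config: PipelineConfig = PipelineConfig(),
) -> ComparisonReport:
    """Five-way selector comparison under repeated-shuffle evaluation.

    Each method's selector is re-run on a freshly shuffled copy of the data
    per repeat and its subset cross-validated; rows carry the mean selected
    gene count and mean accuracy. A selector failure is recorded in the row,
    not fatal to the run.
    """
    if not methods:
        raise ValueError("methods must be nonempty")
    rows = []
    details: dict[str, EvaluationResult] = {}
    for method in methods:
        selector = make_selector(method, config)
        try:
            res = repeated_shuffle_evaluation(
                ds,
                selector,
                folds=config.folds,
                repeats=config.repeats,
                base_seed=config.base_seed,
            )
            details[method] = res
            rows.append(
                {
                    "method": method,
                    "n_genes": res.n_genes,
                    "accuracy": res.mean_accuracy,
                    "failed_repeats": len(res.failed_repeats),
                    "error": "",
                }
            )
        except Exception as exc:  # a broken selector must not kill the table
            rows.append(
                {
                    "method": method,
                    "n_genes": float("nan"),
                    "accuracy": float("nan"),
                    "failed_repeats": config.repeats,
                    "error": str(exc),
                }
            )
    return ComparisonReport(rows=pd.DataFrame(rows), config=config, details=details)
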
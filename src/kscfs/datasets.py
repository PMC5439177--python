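"""Labeled expression matrices: containers, file IO, standardization, simulation.

The central container is :class:`ExpressionDataset`, a samples x genes real
matrix with a binary class label per sample (``positive`` = tumor,
``negative`` = normal in the cancer-microarray setting this package targets).
Datasets load from delimited text (CSV/TSV) or Weka-style ARFF, are Z-score
standardized gene-wise before any selection, and can be simulated with
planted ground truth so that every selection stage is testable without
external microarray downloads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff

__all__ = [
    "ExpressionDataset",
    "SyntheticSpec",
    "load_expression_table",
    "save_expression_table",
    "zscore_standardize",
    "generate_synthetic",
    "paper_like_spec",
]


class DataError(ValueError):
    """Raised for malformed input tables (bad labels, non-numeric cells...)."""


@dataclass(frozen=True)
class ExpressionDataset:
    """A binary-class expression matrix.

    Parameters
    ----------
    values
        Real matrix, shape ``(n_samples, n_genes)``; rows are samples.
    labels
        Integer vector in ``{0, 1}``; 1 is the positive class.
    gene_ids, sample_ids
        Unique string identifiers for columns and rows.
    label_names
        Mapping from ``"positive"``/``"negative"`` to the original label
        strings, recording how the file's labels were oriented.
    constant_genes
        Identifiers of genes flagged as constant during standardization.
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    label_names: dict = field(default_factory=lambda: {"positive": "1", "negative": "0"})
    constant_genes: tuple[str, ...] = ()

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        self.validate()

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.labels) != n:
            raise DataError(f"{len(self.labels)} labels for {n} samples")
        if len(self.gene_ids) != p:
            raise DataError(f"{len(self.gene_ids)} gene ids for {p} columns")
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.gene_ids)) != p:
            dupes = pd.Index(self.gene_ids)
            raise DataError(
                "duplicate gene ids: " + ", ".join(sorted(set(dupes[dupes.duplicated()])))
            )
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite expression value at sample {self.sample_ids[bad[0]]!r}, "
                f"gene {self.gene_ids[bad[1]]!r}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise DataError("labels must be coded 0/1")
        n_pos = int(self.labels.sum())
        if n_pos < 2 or n - n_pos < 2:
            raise DataError(
                f"each class needs >= 2 samples (got {n_pos} positive, {n - n_pos} negative)"
            )

    # -- basic views ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return self.n_samples - self.n_pos

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def gene_column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def class_split(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Positive-class and negative-class values of gene column ``j``."""
        col = self.values[:, j]
        mask = self.labels == 1
        return col[mask], col[~mask]

    def restrict_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        idx = [self.gene_index(g) for g in gene_ids]
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=tuple(gene_ids),
            constant_genes=tuple(g for g in self.constant_genes if g in set(gene_ids)),
        )

    def shuffled(self, seed: int) -> "ExpressionDataset":
        """Sample order permuted by a seeded RNG (labels travel with rows)."""
        perm = np.random.default_rng(seed).permutation(self.n_samples)
        return replace(
            self,
            values=self.values[perm],
            labels=self.labels[perm],
            sample_ids=tuple(self.sample_ids[i] for i in perm),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.gene_ids))
        raw = np.where(self.labels == 1, self.label_names["positive"], self.label_names["negative"])
        df["class"] = raw
        return df


def _orient_labels(raw: pd.Series, positive_label: str | None) -> tuple[np.ndarray, dict]:
    levels = sorted({str(v) for v in raw})
    if len(levels) != 2:
        raise DataError(
            f"label column must have exactly two distinct values, found {len(levels)}: "
            + ", ".join(repr(v) for v in levels)
        )
    if positive_label is None:
        positive = levels[1]  # lexicographically larger string
    else:
        if str(positive_label) not in levels:
            raise DataError(f"positive label {positive_label!r} not among {levels}")
        positive = str(positive_label)
    negative = levels[0] if positive == levels[1] else levels[1]
    y = (raw.astype(str) == positive).to_numpy().astype(int)
    return y, {"positive": positive, "negative": negative}


def _from_frame(
    df: pd.DataFrame,
    label_column: str,
    positive_label: str | None,
    impute: str | None,
    source: str,
) -> ExpressionDataset:
    if label_column not in df.columns:
        raise DataError(f"label column {label_column!r} not in {source}")
    y, names = _orient_labels(df[label_column], positive_label)
    expr = df.drop(columns=[label_column])
    for col in expr.columns:
        coerced = pd.to_numeric(expr[col], errors="coerce")
        fresh_na = coerced.isna() & expr[col].notna()
        if fresh_na.any():
            row = expr.index[fresh_na][0]
            raise DataError(
                f"non-numeric expression cell at row {row!r}, column {col!r} in {source}"
            )
        expr[col] = coerced
    if expr.isna().any().any():
        if impute == "median":
            expr = expr.fillna(expr.median())
        else:
            rows, cols = np.where(expr.isna())
            raise DataError(
                f"missing value at row {expr.index[rows[0]]!r}, "
                f"column {expr.columns[cols[0]]!r} in {source} "
                "(pass impute='median' to impute per-gene medians)"
            )
    return ExpressionDataset(
        values=expr.to_numpy(dtype=float),
        labels=y,
        gene_ids=tuple(str(c) for c in expr.columns),
        sample_ids=tuple(str(i) for i in expr.index),
        label_names=names,
    )


def load_expression_table(
    path: str | Path,
    format: Literal["csv", "tsv", "arff", "auto"] = "auto",
    label_column: str = "class",
    positive_label: str | None = None,
    impute: str | None = None,
) -> ExpressionDataset:
    """Read a labeled expression matrix from CSV, TSV or ARFF.

    CSV/TSV layout: header row of gene ids plus the label column; one row per
    sample; an optional unnamed first column supplies sample ids. ARFF: one
    numeric attribute per gene and one nominal class attribute (the dialect
    Weka writes). The lexicographically larger label string maps to the
    positive class unless ``positive_label`` overrides it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if format == "auto":
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in ("csv", "tsv", "arff") else "csv"
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        first = str(df.columns[0])
        if first in ("", "Unnamed: 0", "sample_id", "sample", "id"):
            df = df.set_index(df.columns[0])
        else:
            df.index = [f"s{i}" for i in range(len(df))]
        return _from_frame(df, label_column, positive_label, impute, str(path))
    if format == "arff":
        data, meta = scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
        df.index = [f"s{i}" for i in range(len(df))]
        return _from_frame(df, label_column, positive_label, impute, str(path))
    raise ValueError(f"unknown format {format!r}")


def save_expression_table(
    ds: ExpressionDataset,
    path: str | Path,
    format: Literal["csv", "tsv", "arff", "auto"] = "auto",
    label_column: str = "class",
) -> None:
    """Write a dataset back to CSV/TSV/ARFF at full float precision."""
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in ("csv", "tsv", "arff") else "csv"
    df = ds.to_frame().rename(columns={"class": label_column})
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df.to_csv(path, sep=sep, float_format="%.17g")
        return
    if format == "arff":
        buf = io.StringIO()
        buf.write("@RELATION expression\n\n")
        for g in ds.gene_ids:
            buf.write(f"@ATTRIBUTE {g} NUMERIC\n")
        neg, pos = ds.label_names["negative"], ds.label_names["positive"]
        buf.write(f"@ATTRIBUTE {label_column} {{{neg},{pos}}}\n\n@DATA\n")
        for i in range(ds.n_samples):
            cells = [f"{v:.17g}" for v in ds.values[i]]
            cells.append(pos if ds.labels[i] == 1 else neg)
            buf.write(",".join(cells) + "\n")
        path.write_text(buf.getvalue())
        return
    raise ValueError(f"unknown format {format!r}")


def zscore_standardize(ds: ExpressionDataset) -> ExpressionDataset:
    """Z-score each gene over all samples pooled (mean 0, sd 1, ddof=1).

    Standardization is class-blind by design: scaling within classes would
    leak the labels into the features before selection. Constant genes map to
    all-zero columns and are recorded in ``constant_genes`` rather than
    rejected — real microarray exports contain flat probes and every
    downstream test treats them as "no difference".
    """
    mu = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=1)
    flat = sd == 0
    safe_sd = np.where(flat, 1.0, sd)
    z = (ds.values - mu) / safe_sd
    z[:, flat] = 0.0
    flagged = tuple(g for g, f in zip(ds.gene_ids, flat) if f)
    return replace(ds, values=z, constant_genes=flagged)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic expression-matrix generator.

    The generator emulates the structure of binary-class microarray studies:
    a small minority of genes carry a between-class location shift
    (``shift_effect``, in units of the within-class standard deviation) or a
    pure scale change (``scale_ratio`` = positive-class sd / negative-class
    sd, with equal means — detectable by a distribution test, invisible to
    mean/rank tests); some genes are noisy near-copies of informative genes;
    the rest are pure noise with identical class distributions.
    """

    n_pos: int = 40
    n_neg: int = 40
    n_informative_shift: int = 20
    shift_effect: float = 2.0
    n_informative_scale: int = 10
    scale_ratio: float = 3.0
    n_redundant: int = 15
    redundancy_noise: float = 0.05
    n_noise: int = 1955
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_pos,
            self.n_neg,
            self.n_informative_shift,
            self.n_informative_scale,
            self.n_redundant,
            self.n_noise,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("each class needs >= 2 samples")
        if self.shift_effect < 0 or self.redundancy_noise < 0:
            raise ValueError("shift_effect and redundancy_noise must be >= 0")
        if self.scale_ratio <= 0:
            raise ValueError("scale_ratio must be > 0")
        if self.n_redundant > 0 and self.n_informative_shift + self.n_informative_scale == 0:
            raise ValueError("redundant genes need at least one informative gene to copy")

    @property
    def n_genes(self) -> int:
        return self.n_informative_shift + self.n_informative_scale + self.n_redundant + self.n_noise


def paper_like_spec(seed: int = 0) -> SyntheticSpec:
    """The default study conditions: 2,000 genes (20 mean-shift at 2 sd,
    10 scale-changed at ratio 3, 15 redundant near-copies, 1,955 noise),
    40 + 40 samples — the scale of a small two-class microarray cohort."""
    return SyntheticSpec(seed=seed)


def generate_synthetic(spec: SyntheticSpec) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Simulate an expression matrix with planted gene roles.

    Returns the dataset and a ground-truth table with one row per gene:
    ``gene_id``, ``role`` in {shift, scale, redundant, noise}, and ``source``
    (the informative gene a redundant gene copies, empty otherwise).

    All within-class noise is standard normal. Shift genes have class means
    separated by ``shift_effect``; scale genes have equal means and a
    positive/negative sd ratio of ``scale_ratio``. Identical spec and seed
    give bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    labels = np.concatenate([np.ones(spec.n_pos, int), np.zeros(spec.n_neg, int)])
    pos = labels == 1

    cols: list[np.ndarray] = []
    roles: list[tuple[str, str, str]] = []
    width = max(4, len(str(spec.n_genes)))

    def gid(i: int) -> str:
        return f"g{i:0{width}d}"

    informative: list[int] = []
    for _ in range(spec.n_informative_shift):
        col = rng.standard_normal(n)
        col[pos] += spec.shift_effect
        informative.append(len(cols))
        roles.append((gid(len(cols)), "shift", ""))
        cols.append(col)
    for _ in range(spec.n_informative_scale):
        col = rng.standard_normal(n)
        col[pos] *= spec.scale_ratio
        informative.append(len(cols))
        roles.append((gid(len(cols)), "scale", ""))
        cols.append(col)
    for r in range(spec.n_redundant):
        src = informative[r % len(informative)]
        col = cols[src] + spec.redundancy_noise * rng.standard_normal(n)
        roles.append((gid(len(cols)), "redundant", gid(src)))
        cols.append(col)
    for _ in range(spec.n_noise):
        roles.append((gid(len(cols)), "noise", ""))
        cols.append(rng.standard_normal(n))

    values = np.column_stack(cols) if cols else np.empty((n, 0))
    ds = ExpressionDataset(
        values=values,
        labels=labels,
        gene_ids=tuple(r[0] for r in roles),
        sample_ids=tuple(f"s{i:03d}" for i in range(n)),
        label_names={"positive": "pos", "negative": "neg"},
    )
    truth = pd.DataFrame(roles, columns=["gene_id", "role", "source"])
    return ds, truth
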
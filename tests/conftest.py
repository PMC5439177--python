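import numpy as np
import pytest

from kscfs import ExpressionDataset, SyntheticSpec, generate_synthetic, zscore_standardize


def make_dataset(values, labels, gene_prefix="g"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionDataset(
        values=values,
        labels=np.asarray(labels, dtype=int),
        gene_ids=tuple(f"{gene_prefix}{j}" for j in range(p)),
        sample_ids=tuple(f"s{i}" for i in range(n)),
    )


@pytest.fixture
def tiny_dataset():
    """4 samples x 2 genes, balanced classes."""
    return make_dataset([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0], [4.0, 8.0]], [1, 1, 0, 0])


@pytest.fixture
def small_informative():
    """Standardized 80-sample matrix: 5 shift + 3 scale + 4 redundant + 50 noise."""
    spec = SyntheticSpec(
        n_pos=40,
        n_neg=40,
        n_informative_shift=5,
        shift_effect=2.0,
        n_informative_scale=3,
        scale_ratio=3.0,
        n_redundant=4,
        redundancy_noise=0.05,
        n_noise=50,
        seed=1,
    )
    ds, truth = generate_synthetic(spec)
    return zscore_standardize(ds), truth
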
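import numpy as np
import pandas as pd
import pytest

from crosspipe import CountMatrix, SampleSheet, simulate_bulk_counts


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 2 samples with easily checked library sizes."""
    df = pd.DataFrame(
        {"s1": [3, 5, 7], "s2": [4, 6, 8]},
        index=["g1", "g2", "g3"],
    )
    return CountMatrix(df)


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"],
                "group": ["A", "A", "A", "B", "B", "B"],
            }
        )
    )


@pytest.fixture(scope="session")
def nb_dataset():
    """Moderate-size NB dataset with planted signal, shared across tests."""
    m, s, truth = simulate_bulk_counts(
        600,
        {"A": 5, "B": 5},
        lfc_map={f"g{i + 1:04d}": 2.0 for i in range(60)},
        low_count_fraction=0.2,
        seed=42,
    )
    return m, s, truth


def make_counts(values, genes=None, samples=None) -> CountMatrix:
    arr = np.asarray(values)
    genes = genes or [f"g{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=samples))
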
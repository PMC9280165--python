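import numpy as np
import pandas as pd
import pytest

from geitools import build_ge_matrix, load_fixture_table2


@pytest.fixture(scope="session")
def fixture_summary() -> pd.DataFrame:
    return load_fixture_table2()


@pytest.fixture(scope="session")
def ge_matrices(fixture_summary):
    return {cond: build_ge_matrix(fixture_summary, cond)
            for cond in (5, 8, 13, 18)}


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_summary(rng, conditions=2, tissues=3, genes=3, n=3):
    """A complete balanced summary table with positive random cells."""
    rows = []
    for c in range(conditions):
        for t in range(tissues):
            for g in range(genes):
                rows.append((10 * (c + 1), f"T{t}", f"G{g}",
                             rng.uniform(1, 100), rng.uniform(0.1, 5), n))
    return pd.DataFrame(
        rows, columns=["condition", "tissue", "gene", "mean", "sd", "n"])
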
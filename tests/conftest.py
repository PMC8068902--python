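import numpy as np
import pandas as pd
import pytest

from crossclust import simulate
from crossclust.tables import (
    BiomarkerTable,
    CountTable,
    MetaboliteTable,
    SampleDesign,
)


@pytest.fixture
def small_counts() -> CountTable:
    return CountTable(
        pd.DataFrame(
            [[2, 3, 5], [1, 4, 5], [0, 10, 10]],
            index=["s1", "s2", "s3"],
            columns=["gA", "gB", "gC"],
        )
    )


@pytest.fixture
def small_design() -> SampleDesign:
    frame = pd.DataFrame(
        {
            "fat": ["HFD"] * 4 + ["HFD"] * 4 + ["LFD"] * 4 + ["LFD"] * 4,
            "xos": (["no"] * 4 + ["yes"] * 4) * 2,
        },
        index=[f"s{i}" for i in range(16)],
    )
    return SampleDesign(frame)


@pytest.fixture
def small_metabolites(small_design) -> MetaboliteTable:
    rng = np.random.default_rng(3)
    values = rng.lognormal(1.0, 0.5, size=(16, 4))
    return MetaboliteTable(
        pd.DataFrame(values, index=small_design.sample_ids,
                     columns=["m1", "m2", "m3", "m4"])
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """One synthetic study-scale dataset shared across tests."""
    return simulate.generate(simulate.SimConfig(sigma=0.05, seed=11))


def block_diagonal(sizes_rows, sizes_cols, constants=None):
    """Noise-free block-diagonal matrix with constant positive blocks."""
    from scipy.linalg import block_diag

    k = len(sizes_rows)
    constants = constants or [1.0] * k
    return block_diag(
        *[np.full((r, c), v) for r, c, v in zip(sizes_rows, sizes_cols, constants)]
    )
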
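import numpy as np
import pandas as pd
import pytest

from colonscape.tables import AsvTable


@pytest.fixture
def toy_table() -> AsvTable:
    counts = pd.DataFrame(
        {"s1": [5, 0, 2, 0, 1], "s2": [10, 10, 10, 10, 0], "s3": [0, 3, 0, 7, 0]},
        index=[f"t{i}" for i in range(5)],
    )
    return AsvTable(counts)


@pytest.fixture
def random_tables():
    """Twenty random 10-feature x 12-sample count tables."""
    rng = np.random.default_rng(42)
    tables = []
    for _ in range(20):
        counts = rng.integers(0, 50, size=(10, 12))
        counts[:, counts.sum(axis=0) == 0] += 1
        tables.append(
            AsvTable(pd.DataFrame(
                counts,
                index=[f"t{i}" for i in range(10)],
                columns=[f"s{j}" for j in range(12)],
            ))
        )
    return tables
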
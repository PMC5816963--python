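import numpy as np
import pandas as pd
import pytest

from coremic.table import AbundanceTable, GroupMap


@pytest.fixture
def small_table() -> AbundanceTable:
    df = pd.DataFrame(
        [[1.0, 2.0, 0.0], [3.0, 4.0, 5.0], [0.0, 5.0, 1.0]],
        index=[
            "k__Bacteria;p__Proteobacteria",
            "k__Bacteria;p__Bacteroidetes",
            "k__Bacteria;p__Acidobacteria",
        ],
        columns=["S1", "S2", "S3"],
    )
    return AbundanceTable(data=df, provenance="small")


@pytest.fixture
def swg_groups() -> GroupMap:
    md = pd.DataFrame(
        {"Plant": ["Swg", "Swg", "NonSwg", "NonSwg", "Corn"]},
        index=["A", "B", "C", "D", "E"],
    )
    return GroupMap(metadata=md, group_column="Plant", interest="Swg")


def random_table(rng: np.random.Generator, n_rows=6, n_cols=4) -> AbundanceTable:
    """Small random integer table with possibly duplicated taxonomies."""
    phyla = ["Proteobacteria", "Bacteroidetes", "Firmicutes"]
    idx = []
    for i in range(n_rows):
        p = phyla[rng.integers(len(phyla))]
        idx.append(f"k__Bacteria;p__{p};g__G{i}")
    counts = rng.integers(0, 20, size=(n_rows, n_cols)).astype(float)
    cols = [f"S{j}" for j in range(n_cols)]
    return AbundanceTable(data=pd.DataFrame(counts, index=idx, columns=cols))
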
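import numpy as np
import pandas as pd
import pytest
import skbio

from guyot.data_io import OtuTable, PhyloTree, SampleFrame


@pytest.fixture
def four_taxon_tree() -> PhyloTree:
    """Balanced 4-leaf tree with unit branches: d(A,B)=2, d(A,C)=4."""
    return PhyloTree(skbio.TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"]))


@pytest.fixture
def small_table() -> OtuTable:
    counts = pd.DataFrame(
        [[5, 3, 0, 2], [0, 4, 4, 2], [1, 1, 1, 7]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C", "D"],
    )
    return OtuTable(counts)


@pytest.fixture
def random_table() -> OtuTable:
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 30, size=(6, 12))
    counts[:, 0] += 1  # no empty samples
    return OtuTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(6)],
            columns=[f"O{j}" for j in range(12)],
        )
    )


@pytest.fixture
def layered_meta() -> SampleFrame:
    meta = pd.DataFrame(
        {
            "site": ["A", "A", "B", "B", "A", "B"],
            "layer": ["surface", "deep", "surface", "deep", "surface", "deep"],
            "depth": [5.0, 2000.0, 5.0, 2000.0, 5.0, 2000.0],
            "temperature": [28.0, 2.0, 27.5, 2.1, 28.2, 1.9],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return SampleFrame(meta)
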
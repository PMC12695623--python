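import numpy as np
import pandas as pd
import pytest

from cmapscreen import RankMatrix, RankedInstance, SignedSignature


def make_instance(ranks, instance_id="inst1", compound="drugA"):
    """RankedInstance from a rank vector over genes g1..gN."""
    genes = [f"g{i}" for i in range(1, len(ranks) + 1)]
    return RankedInstance(
        instance_id=instance_id,
        compound=compound,
        dose="10uM",
        cell_line="MCF7",
        ranks=pd.Series(list(ranks), index=genes),
    )


def instance_with_tag_positions(n_genes, positions, **kwargs):
    """Instance whose genes t1..tk occupy the given rank positions."""
    ranks = np.arange(1, n_genes + 1)
    inst = make_instance(ranks, **kwargs)
    genes = list(inst.ranks.index)
    tags = [genes[p - 1] for p in positions]
    return inst, tags


@pytest.fixture
def small_matrix():
    """3-gene, 2-instance compendium with hand-written rankings."""
    ranks = pd.DataFrame(
        {"i1": [1, 2, 3], "i2": [3, 1, 2]}, index=["gA", "gB", "gC"]
    )
    meta = pd.DataFrame(
        {
            "instance_id": ["i1", "i2"],
            "compound": ["drugA", "drugB"],
            "dose": ["1uM", "2uM"],
            "cell_line": ["MCF7", "PC3"],
        }
    )
    return RankMatrix(ranks, meta)


@pytest.fixture
def de_table():
    return pd.DataFrame(
        {
            "gene": [f"g{i}" for i in range(1, 7)],
            "log2fc": [2.0, 1.6, 0.5, -0.2, -1.7, -2.1],
            "adj_p": [0.01] * 6,
        }
    )
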
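import networkx as nx
import numpy as np
import pandas as pd
import pytest

from activemod.preprocess import ExpressionMatrix


@pytest.fixture
def wnt_motif_graph():
    """The interactor motif around RACGAP1: AURKA is a direct neighbor,
    CTNNB1 and CDKN1A sit two steps away via CCNB1 and PLK1."""
    g = nx.Graph()
    for u, v in [
        ("AURKA", "RACGAP1"),
        ("RACGAP1", "CCNB1"),
        ("CCNB1", "CTNNB1"),
        ("RACGAP1", "PLK1"),
        ("PLK1", "CDKN1A"),
    ]:
        g.add_edge(u, v, confidence=0.9)
    return g


@pytest.fixture
def small_matrix():
    """4-sample, 4-probe matrix with explicit present calls."""
    values = pd.DataFrame(
        np.arange(16, dtype=float).reshape(4, 4),
        index=[f"p{i}" for i in range(4)],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(
        ["case", "case", "control", "control"], index=values.columns, name="group"
    )
    calls = pd.DataFrame(True, index=values.index, columns=values.columns)
    return ExpressionMatrix(values, groups, calls)
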
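import networkx as nx
import numpy as np
import pandas as pd
import pytest

from genesurrounder import ExpressionStudy, GeneNetwork


@pytest.fixture
def path_net() -> GeneNetwork:
    """A -- B -- C -- D."""
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
    return GeneNetwork(g)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def toy_study(values: np.ndarray, genes, labels) -> ExpressionStudy:
    samples = [f"S{k}" for k in range(values.shape[1])]
    return ExpressionStudy(
        pd.DataFrame(values, index=list(genes), columns=samples),
        pd.Series(list(labels), index=samples),
    )


@pytest.fixture
def balanced_study(rng) -> ExpressionStudy:
    """8 genes x 12 samples, 6 per class, pure noise."""
    return toy_study(
        rng.standard_normal((8, 12)),
        [f"g{k}" for k in range(8)],
        ["low"] * 6 + ["high"] * 6,
    )
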
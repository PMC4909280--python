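import networkx as nx
import numpy as np
import pandas as pd
import pytest

from prizenet import ExpressionAtlas, constraint_p_from_z


@pytest.fixture
def chain_graph():
    """A(+2) - X(-1) - B(+3)."""
    G = nx.Graph([("A", "X"), ("X", "B")])
    w = {"A": 2.0, "X": -1.0, "B": 3.0}
    return G, w


@pytest.fixture
def score_frame():
    def make(genes, z):
        z = np.asarray(z, dtype=float)
        return pd.DataFrame(
            {"z": z, "p": constraint_p_from_z(z)},
            index=pd.Index(list(genes), name="gene_id"),
        )

    return make


@pytest.fixture
def small_atlas():
    """Two tissues x 3 replicates, 4 genes, no noise: deterministic means."""
    genes = ["g1", "g2", "g3", "g4"]
    samples = ["a_r1", "a_r2", "a_r3", "b_r1", "b_r2", "b_r3"]
    rng = np.random.default_rng(0)
    X = 8.0 + rng.normal(0, 0.3, (4, 6))
    X[0, :3] += 2.0  # g1 up in tissue a
    matrix = pd.DataFrame(X, index=genes, columns=samples)
    sample_map = pd.Series(["a"] * 3 + ["b"] * 3, index=samples)
    return ExpressionAtlas(matrix=matrix, sample_map=sample_map)


def random_weighted_graph(n, density, rng, n_signal=3, scale=2.0):
    """Random instance for solver comparisons: Normal(0, scale) weights with
    ``n_signal`` nodes forced positive."""
    nodes = [f"n{i:02d}" for i in range(n)]
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                G.add_edge(nodes[i], nodes[j])
    w = {v: float(rng.normal(0, scale)) for v in nodes}
    for i in rng.choice(n, size=n_signal, replace=False):
        w[nodes[i]] = abs(w[nodes[i]]) or scale / 2
    return G, w
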
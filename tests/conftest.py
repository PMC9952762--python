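import numpy as np
import pandas as pd
import pytest

from omicsforest import InteractionNetwork, OmicsMatrix


@pytest.fixture
def small_counts():
    """2x2 protein spectral-count matrix with one KO and one WT sample."""
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0]], index=["P1", "P2"], columns=["WT_1", "KO_1"]
    )
    return OmicsMatrix(
        layer="protein",
        values=values,
        condition={"WT_1": "WT", "KO_1": "KO"},
        protein_lengths={"P1": 100, "P2": 200},
    )


def make_matrix(values, feature_ids, layer="transcript", n_wt=None, lengths=None):
    """Matrix helper: first half of the columns WT, second half KO."""
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    n_wt = n_samples // 2 if n_wt is None else n_wt
    samples = [f"WT_{i+1}" for i in range(n_wt)] + [f"KO_{i+1}" for i in range(n_samples - n_wt)]
    condition = {s: ("WT" if s.startswith("WT") else "KO") for s in samples}
    return OmicsMatrix(
        layer=layer,
        values=pd.DataFrame(values, index=feature_ids, columns=samples),
        condition=condition,
        protein_lengths=lengths,
    )


def path_network(prizes=(5.0, 0.0, 5.0), costs=(0.4, 0.4)):
    """The worked path instance A–B–C with configurable prizes and costs."""
    net = InteractionNetwork()
    for name, p in zip("ABC", prizes):
        net.add_node(name, "gene", prize=p, measured=p > 0)
    net.add_edge("A", "B", 0.5)
    net.add_edge("B", "C", 0.5)
    for (u, v), c in zip((("A", "B"), ("B", "C")), costs):
        net.graph.edges[u, v]["cost"] = c
    return net


def random_prized_network(rng, n, p_edge=0.4, prize_hi=3.0):
    """Random instance with U[0, prize_hi] prizes and U[0,1] edge costs."""
    net = InteractionNetwork()
    names = [f"N{i:02d}" for i in range(n)]
    for v in names:
        net.add_node(v, "gene", prize=float(rng.uniform(0, prize_hi)))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                net.add_edge(names[i], names[j], 1.0)
                net.graph.edges[names[i], names[j]]["cost"] = float(rng.uniform(0, 1))
    return net
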
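import numpy as np
import pytest

from netpea.network import GeneNetwork


def random_network(seed: int, n: int = 50, p: float = 0.08) -> GeneNetwork:
    """Erdos-Renyi test graph; every node registered, isolates possible."""
    rng = np.random.default_rng(seed)
    names = [f"N{i:03d}" for i in range(n)]
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    if not mask.any():
        mask[0] = True
    edges = [(names[i], names[j]) for i, j in zip(iu[mask], ju[mask])]
    return GeneNetwork.from_edges(edges, extra_nodes=names)


@pytest.fixture
def single_edge() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B")])


@pytest.fixture
def triangle() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_abc() -> GeneNetwork:
    return GeneNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star() -> GeneNetwork:
    return GeneNetwork.from_edges([("H", leaf) for leaf in "ABCD"])
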
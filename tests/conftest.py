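import numpy as np
import pytest

from dgcd.network_io import BipartiteGraph
from dgcd.synthetic_data import GeneratorConfig, generate_network


def bip(id, edges, set_a=None, set_b=None):
    """Build a BipartiteGraph from (source, target) pairs, inferring sets."""
    edges = frozenset(edges)
    if set_a is None:
        set_a = tuple(sorted({v for _, v in edges}))
    if set_b is None:
        set_b = tuple(sorted({u for u, _ in edges}))
    return BipartiteGraph(id=id, set_a=tuple(set_a), set_b=tuple(set_b), edges=edges)


def random_bipartite(seed, n_sources=7, n_targets=7, connectance=0.4, skew=0.5):
    """Small random bipartite graph passing the default size filter."""
    return generate_network(
        GeneratorConfig(
            n_sources=n_sources,
            n_targets=n_targets,
            connectance=connectance,
            degree_skew=skew,
            seed=seed,
        )
    )


def random_raw_bipartite(rng, net_id, side_range=(5, 13), conn_range=(0.1, 0.9)):
    """Unfiltered Bernoulli bipartite graph (no giant-component/size filter);
    resamples until at least one edge appears."""
    while True:
        n_s = int(rng.integers(*side_range))
        n_t = int(rng.integers(*side_range))
        c = float(rng.uniform(*conn_range))
        adj = rng.random((n_s, n_t)) < c
        if adj.any():
            break
    sources = tuple(f"s{i:02d}" for i in range(n_s))
    targets = tuple(f"t{j:02d}" for j in range(n_t))
    edges = frozenset((sources[i], targets[j]) for i, j in zip(*np.nonzero(adj)))
    return BipartiteGraph(net_id, targets, sources, edges)


@pytest.fixture
def single_edge():
    return bip("edge", {("u", "v")})


@pytest.fixture
def out_star():
    return bip("star", {("u", "v1"), ("u", "v2"), ("u", "v3")})


@pytest.fixture
def small_collection():
    """Ten deterministic small random bipartite networks with distinct ids."""
    graphs = []
    for s in range(10):
        g = random_bipartite(100 + s)
        g.id = f"net{s:02d}"
        graphs.append(g)
    return graphs
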
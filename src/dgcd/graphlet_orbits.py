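"""Directed 2-3-node graphlets and per-node orbit counting.

A graphlet is a small connected *induced* directed subgraph pattern; an
orbit is an equivalence class of node positions within a graphlet under its
automorphisms. Six directed graphlets exist on 2-3 nodes (without
reciprocal edges), carrying 13 orbits in total:

==========  =======================  =================================
graphlet    structure                orbits (node position)
==========  =======================  =================================
G0          u -> v                   0 (source), 1 (target)
G1          u -> v -> w              2 (start), 3 (middle), 4 (end)
G2          u -> w <- v  (in-star)   5 (periphery), 6 (center)
G3          v <- u -> w  (out-star)  7 (center), 8 (periphery)
G4          3-cycle                  9
G5          feed-forward triangle    10 (source), 11 (middle), 12 (sink)
==========  =======================  =================================

In a uniformly oriented bipartite graph no directed 2-path exists, so only
G0, G2 and G3 occur; their six orbits (0, 1, 5, 6, 7, 8) are the subset the
6-orbit distance variant uses. For bipartite inputs :func:`count_orbits`
uses closed-form degree combinatorics; :func:`count_orbits_bruteforce`
enumerates node subsets and classifies induced subgraphs, serving as the
independent oracle (and handling arbitrary directed inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .network_io import BipartiteGraph

__all__ = [
    "Graphlet",
    "OrbitCatalog",
    "OrbitCountMatrix",
    "DEFAULT_CATALOG",
    "N_ORBITS",
    "BIPARTITE_ORBITS",
    "count_orbits",
    "count_orbits_bruteforce",
    "write_orbit_counts",
    "read_orbit_counts",
]

N_ORBITS = 13
#: Orbits of the graphlets realizable in a uniformly oriented bipartite
#: graph (G0, G2, G3); the orbit subset of the 6-orbit distance variant.
BIPARTITE_ORBITS: tuple[int, ...] = (0, 1, 5, 6, 7, 8)

DegPair = tuple[int, int]


@dataclass(frozen=True)
class Graphlet:
    """One directed graphlet: node positions 0..n-1, edges, orbit per position."""

    name: str
    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    orbit_of: tuple[int, ...]  # orbit id per node position

    def degree_pairs(self) -> list[DegPair]:
        indeg = [0] * self.n_nodes
        outdeg = [0] * self.n_nodes
        for u, v in self.edges:
            outdeg[u] += 1
            indeg[v] += 1
        return [(indeg[i], outdeg[i]) for i in range(self.n_nodes)]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


Signature = tuple[DegPair, ...]


class OrbitCatalog:
    """The six 2-3-node directed graphlets and their 13 orbits.

    Each graphlet is identified, among connected induced subgraphs, by the
    sorted multiset of within-subgraph (in-degree, out-degree) pairs; within
    a graphlet each orbit corresponds to a distinct degree pair. Both facts
    are asserted at construction and verified exhaustively against VF2
    isomorphism in the test suite.
    """

    def __init__(self, graphlets: Sequence[Graphlet]):
        self.graphlets = tuple(graphlets)
        self.n_orbits = 1 + max(o for g in graphlets for o in g.orbit_of)
        self._sig_to_idx: dict[Signature, int] = {}
        self._orbit_by_degpair: dict[tuple[int, DegPair], int] = {}
        for gi, g in enumerate(self.graphlets):
            pairs = g.degree_pairs()
            sig = tuple(sorted(pairs))
            if any(p == (0, 0) for p in pairs):
                raise ValueError(f"{g.name}: disconnected graphlet")
            if sig in self._sig_to_idx:
                raise ValueError(f"{g.name}: degree signature collides")
            self._sig_to_idx[sig] = gi
            for pos, p in enumerate(pairs):
                orb = g.orbit_of[pos]
                prev = self._orbit_by_degpair.setdefault((gi, p), orb)
                if prev != orb:
                    raise ValueError(
                        f"{g.name}: orbit not determined by degree pair {p}"
                    )
            # distinct orbits must map to distinct degree pairs
            if len({p for (i, p) in self._orbit_by_degpair if i == gi}) != len(
                set(g.orbit_of)
            ):
                raise ValueError(f"{g.name}: orbits collapse onto one degree pair")

    def classify(self, signature: Signature) -> int | None:
        """Graphlet index for a degree-pair signature, or None if no match."""
        return self._sig_to_idx.get(signature)

    def orbit(self, graphlet_index: int, degree_pair: DegPair) -> int:
        return self._orbit_by_degpair[(graphlet_index, degree_pair)]


def _default_catalog() -> OrbitCatalog:
    return OrbitCatalog(
        [
            Graphlet("G0", 2, ((0, 1),), (0, 1)),
            Graphlet("G1", 3, ((0, 1), (1, 2)), (2, 3, 4)),
            Graphlet("G2", 3, ((0, 2), (1, 2)), (5, 5, 6)),
            Graphlet("G3", 3, ((0, 1), (0, 2)), (7, 8, 8)),
            Graphlet("G4", 3, ((0, 1), (1, 2), (2, 0)), (9, 9, 9)),
            Graphlet("G5", 3, ((0, 1), (1, 2), (0, 2)), (10, 11, 12)),
        ]
    )


DEFAULT_CATALOG = _default_catalog()


@dataclass
class OrbitCountMatrix:
    """Per-node counts of appearances in each of the 13 orbits."""

    network_id: str
    node_order: tuple[str, ...]
    counts: np.ndarray  # shape (n_nodes, 13), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.node_order), N_ORBITS):
            raise ValidationError(
                f"{self.network_id}: orbit count matrix shape "
                f"{self.counts.shape} != ({len(self.node_order)}, {N_ORBITS})"
            )
        if (self.counts < 0).any():
            raise ValidationError(f"{self.network_id}: negative orbit count")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.node_order), columns=range(N_ORBITS)
        )

    def row(self, node: str) -> np.ndarray:
        return self.counts[self.node_order.index(node)]


def count_orbits(
    g: BipartiteGraph, catalog: OrbitCatalog = DEFAULT_CATALOG
) -> OrbitCountMatrix:
    """Count orbit appearances for every node of a bipartite oriented graph.

    Because graphlets are induced subgraphs and all edges share one
    direction, closed forms hold. For a source u with out-degree d+ and a
    target v with in-degree d-:

    * orbit 0 (edge source) = d+(u); orbit 1 (edge target) = d-(v)
    * orbit 6 (in-star center) = C(d-(v), 2);
      orbit 5 (in-star periphery) = sum over out-neighbors v of (d-(v) - 1)
    * orbit 7 (out-star center) = C(d+(u), 2);
      orbit 8 (out-star periphery) = sum over in-neighbors u of (d+(u) - 1)

    All other orbit columns are identically zero (G1, G4, G5 need a
    directed 2-path, impossible under uniform orientation).
    """
    nodes = g.nodes
    idx = {u: i for i, u in enumerate(nodes)}
    counts = np.zeros((len(nodes), catalog.n_orbits), dtype=np.int64)
    out = g.out_neighbors()
    inn = g.in_neighbors()
    for u in g.sources:
        nbrs = out.get(u, [])
        d = len(nbrs)
        i = idx[u]
        counts[i, 0] = d
        counts[i, 7] = d * (d - 1) // 2
        counts[i, 5] = sum(len(inn[v]) - 1 for v in nbrs)
    for v in g.targets:
        nbrs = inn.get(v, [])
        d = len(nbrs)
        i = idx[v]
        counts[i, 1] = d
        counts[i, 6] = d * (d - 1) // 2
        counts[i, 8] = sum(len(out[u]) - 1 for u in nbrs)
    return OrbitCountMatrix(g.id, nodes, counts)


GraphLike = Union[BipartiteGraph, nx.DiGraph]


def count_orbits_bruteforce(
    g: GraphLike,
    catalog: OrbitCatalog = DEFAULT_CATALOG,
    cap: int = 60,
) -> OrbitCountMatrix:
    """Oracle orbit counter: enumerate all 2- and 3-node induced subgraphs.

    Every node subset's induced directed subgraph is classified against the
    catalog (connected subgraphs only; anything with a reciprocal edge or an
    isolated node matches no graphlet) and each member node's orbit count is
    incremented. Accepts any directed graph, not just bipartite ones.
    Refuses graphs above ``cap`` nodes: this is a test oracle, O(n^3).
    """
    if isinstance(g, BipartiteGraph):
        net_id = g.id
        nodes = list(g.nodes)
        edge_set = set(g.edges)
    else:
        net_id = str(g.graph.get("id", "digraph"))
        nodes = sorted(g.nodes, key=str)
        edge_set = set(g.edges)
    if len(nodes) > cap:
        raise ValidationError(
            f"{net_id}: {len(nodes)} nodes exceeds brute-force cap {cap}"
        )
    idx = {u: i for i, u in enumerate(nodes)}
    counts = np.zeros((len(nodes), catalog.n_orbits), dtype=np.int64)

    for size in (2, 3):
        for sub in combinations(nodes, size):
            pairs = _induced_degree_pairs(sub, edge_set)
            gi = catalog.classify(tuple(sorted(pairs)))
            if gi is None:
                continue
            for node, p in zip(sub, pairs):
                counts[idx[node], catalog.orbit(gi, p)] += 1
    return OrbitCountMatrix(net_id, tuple(nodes), counts)


def _induced_degree_pairs(
    sub: Sequence[str], edge_set: set[tuple[str, str]]
) -> list[DegPair]:
    indeg = [0] * len(sub)
    outdeg = [0] * len(sub)
    for i, u in enumerate(sub):
        for j, v in enumerate(sub):
            if i != j and (u, v) in edge_set:
                outdeg[i] += 1
                indeg[j] += 1
    return [(indeg[i], outdeg[i]) for i in range(len(sub))]


def write_orbit_counts(m: OrbitCountMatrix, path: str | Path) -> Path:
    """Write counts as TSV: node label column + one integer column per orbit."""
    path = Path(path)
    df = m.to_dataframe()
    df.index.name = "node"
    df.to_csv(path, sep="\t")
    return path


def read_orbit_counts(path: str | Path, network_id: str | None = None) -> OrbitCountMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OrbitCountMatrix(
        network_id if network_id is not None else path.stem,
        tuple(str(i) for i in df.index),
        df.to_numpy(dtype=np.int64),
    )
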
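"""Directed graphlet correlation matrices (DGCM) and distances (DGCD).

A network's DGCM holds, for every pair of orbits, the Spearman rank
correlation (average ranks on ties) between the two per-node orbit-count
vectors. The distance between two networks is the Euclidean distance
between the strict upper triangles of their DGCMs — over all 13 orbits
(DGCD-13) or over the 6 orbits realizable in oriented bipartite graphs
(DGCD-6).

In oriented bipartite graphs 7 of the 13 orbit columns are identically
zero, leaving Spearman undefined. The default remedy appends one
pseudo-node whose count is 1 in every orbit before ranking: two all-zero
columns then correlate at exactly +1 and contribute nothing to any
distance. A ``zero_correlation`` policy is offered instead, defining any
correlation involving a zero-variance column as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError
from .graphlet_orbits import BIPARTITE_ORBITS, N_ORBITS, OrbitCountMatrix, count_orbits
from .network_io import BipartiteGraph, NetworkRecord

__all__ = [
    "DGCM",
    "DistanceMatrix",
    "DGCD13_ORBITS",
    "DGCD6_ORBITS",
    "ZERO_POLICIES",
    "compute_dgcm",
    "compute_dgcd",
    "pairwise_dgcd",
]

DGCD13_ORBITS: tuple[int, ...] = tuple(range(N_ORBITS))
DGCD6_ORBITS: tuple[int, ...] = BIPARTITE_ORBITS
ZERO_POLICIES = ("pseudo_node", "zero_correlation")


@dataclass
class DGCM:
    """Symmetric matrix of Spearman correlations between orbit-count columns."""

    network_id: str
    orbit_subset: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.orbit_subset = tuple(int(o) for o in self.orbit_subset)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.orbit_subset)
        if self.values.shape != (k, k):
            raise ValidationError(
                f"{self.network_id}: DGCM shape {self.values.shape} != ({k}, {k})"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError(f"{self.network_id}: DGCM not symmetric")
        if np.abs(self.values).max() > 1 + 1e-9:
            raise ValidationError(f"{self.network_id}: DGCM entry outside [-1, 1]")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.orbit_subset), k=1)
        return self.values[iu]

    def to_dataframe(self) -> pd.DataFrame:
        labels = list(self.orbit_subset)
        return pd.DataFrame(self.values, index=labels, columns=labels)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "orbit"
        df.to_csv(path, float_format="%.12g")
        return path


@dataclass
class DistanceMatrix:
    """Symmetric pairwise DGCD matrix over a network collection."""

    network_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.network_ids = tuple(str(i) for i in self.network_ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.network_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} != ({n}, {n})"
            )
        if len(set(self.network_ids)) != n:
            raise ValidationError("duplicate network ids in distance matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if (np.diag(self.values) != 0).any():
            raise ValidationError("distance matrix diagonal not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("negative distances")

    def get(self, id_i: str, id_j: str) -> float:
        i = self.network_ids.index(id_i)
        j = self.network_ids.index(id_j)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(self.network_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)

    def to_long(self) -> pd.DataFrame:
        """Unordered pairs (i < j by position) in long format."""
        rows = []
        for i in range(len(self.network_ids)):
            for j in range(i + 1, len(self.network_ids)):
                rows.append(
                    (self.network_ids[i], self.network_ids[j], self.values[i, j])
                )
        return pd.DataFrame(rows, columns=["id_i", "id_j", "dgcd"])

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.to_dataframe()
        df.index.name = "network_id"
        df.to_csv(path, float_format="%.12g")
        return path

    def write_long_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_long().to_csv(path, sep="\t", index=False, float_format="%.12g")
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float))


def compute_dgcm(
    counts: OrbitCountMatrix,
    orbit_subset: Sequence[int] = DGCD13_ORBITS,
    zero_policy: str = "pseudo_node",
) -> DGCM:
    """Spearman correlation matrix between the selected orbit-count columns.

    With the default ``pseudo_node`` policy one artificial node with count 1
    in every orbit is appended before ranking, so orbit columns that are
    identically zero still rank-correlate (at exactly +1 with each other).
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValidationError(f"zero_policy must be one of {ZERO_POLICIES}")
    subset = tuple(int(o) for o in orbit_subset)
    if counts.counts.shape[0] < 2:
        raise ValidationError(
            f"{counts.network_id}: DGCM requires at least 2 nodes"
        )
    X = counts.counts[:, list(subset)].astype(float)
    if zero_policy == "pseudo_node":
        X = np.vstack([X, np.ones(len(subset))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns raise ConstantInputWarning
        rho = stats.spearmanr(X).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape != (len(subset), len(subset)):  # spearmanr collapses k=2 to a scalar
        r = float(rho.ravel()[0])
        rho = np.array([[1.0, r], [r, 1.0]])
    # Residual NaNs mean a column was constant even after any pseudo-node
    # (all real counts tied at 1); no rank correlation is defined there.
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return DGCM(counts.network_id, subset, rho)


def compute_dgcd(a: DGCM, b: DGCM) -> float:
    """Euclidean distance between the strict upper triangles of two DGCMs."""
    if a.orbit_subset != b.orbit_subset:
        raise ValidationError(
            f"orbit subsets differ: {a.orbit_subset} vs {b.orbit_subset}"
        )
    diff = a.upper_triangle() - b.upper_triangle()
    return float(np.sqrt(np.sum(diff * diff)))


RecordLike = Union[NetworkRecord, BipartiteGraph]


def _as_graph(r: RecordLike) -> BipartiteGraph:
    return r.graph if isinstance(r, NetworkRecord) else r


def pairwise_dgcd(
    records: Sequence[RecordLike],
    orbit_subset: Sequence[int] = DGCD13_ORBITS,
    zero_policy: str = "pseudo_node",
) -> DistanceMatrix:
    """Full symmetric DGCD matrix over a collection.

    Each network's DGCM is computed once; distances are Euclidean between
    the vectorized upper triangles.
    """
    graphs = [_as_graph(r) for r in records]
    if len(graphs) < 2:
        raise ValidationError("pairwise DGCD requires at least 2 networks")
    ids = [g.id for g in graphs]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate network ids: {dups[:5]}")
    triangles = np.stack(
        [
            compute_dgcm(count_orbits(g), orbit_subset, zero_policy).upper_triangle()
            for g in graphs
        ]
    )
    values = squareform(pdist(triangles, metric="euclidean"))
    return DistanceMatrix(tuple(ids), values)
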
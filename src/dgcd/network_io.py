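"""Read, validate, binarize, orient, and filter bipartite networks and metadata.

Networks are unweighted bipartite graphs with two disjoint node sets (for a
plant-pollinator web: plants and pollinators). To make graphlet analysis
directional, every edge of a collection is oriented the same way: one whole
node set acts as the "from" side and the other as the "to" side. Incidence
matrices are binarized at > 0; only the giant (largest weakly connected)
component of each network is analysed, and networks with fewer than
``min_side`` nodes on either side are excluded.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger("dgcd")

__all__ = [
    "BipartiteGraph",
    "NetworkRecord",
    "MetadataRow",
    "read_incidence_matrix",
    "write_incidence_matrix",
    "read_edge_list",
    "giant_component",
    "filter_min_side",
    "read_metadata",
    "write_metadata",
    "attach_metadata",
]


@dataclass
class BipartiteGraph:
    """A directed bipartite network with uniformly oriented edges.

    Parameters
    ----------
    id:
        Collection-unique network identifier.
    set_a:
        Ordered labels of the first node set (rows of an incidence matrix,
        e.g. plants).
    set_b:
        Ordered labels of the second node set (columns, e.g. animals).
    edges:
        Directed edges ``(source, target)``. All edges must point from one
        set to the other, the same way for every edge.
    """

    id: str
    set_a: tuple[str, ...]
    set_b: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        self.set_a = tuple(str(u) for u in self.set_a)
        self.set_b = tuple(str(u) for u in self.set_b)
        self.edges = frozenset((str(u), str(v)) for u, v in self.edges)
        if not self.id:
            raise ValidationError("network id must be non-empty")
        if len(set(self.set_a)) != len(self.set_a):
            raise ValidationError(f"{self.id}: duplicate labels in set_a")
        if len(set(self.set_b)) != len(self.set_b):
            raise ValidationError(f"{self.id}: duplicate labels in set_b")
        a, b = set(self.set_a), set(self.set_b)
        if a & b:
            raise ValidationError(
                f"{self.id}: node sets overlap: {sorted(a & b)[:5]}"
            )
        if not self.edges:
            raise ValidationError(f"{self.id}: network has no edges")
        src_in_a = None
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"{self.id}: self-loop at {u!r}")
            if u in a and v in b:
                this = True
            elif u in b and v in a:
                this = False
            else:
                raise ValidationError(
                    f"{self.id}: edge ({u!r}, {v!r}) does not connect the two sets"
                )
            if src_in_a is None:
                src_in_a = this
            elif src_in_a is not this:
                raise ValidationError(
                    f"{self.id}: edges are not uniformly oriented"
                )
        self._source_in_a: bool = bool(src_in_a)

    # -- derived views -----------------------------------------------------

    @property
    def sources(self) -> tuple[str, ...]:
        """Labels of the set every edge points from."""
        return self.set_a if self._source_in_a else self.set_b

    @property
    def targets(self) -> tuple[str, ...]:
        """Labels of the set every edge points to."""
        return self.set_b if self._source_in_a else self.set_a

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.set_a + self.set_b

    def out_neighbors(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = defaultdict(list)
        for u, v in sorted(self.edges):
            out[u].append(v)
        return out

    def in_neighbors(self) -> dict[str, list[str]]:
        inn: dict[str, list[str]] = defaultdict(list)
        for u, v in sorted(self.edges):
            inn[v].append(u)
        return inn

    def reverse(self) -> "BipartiteGraph":
        """Same topology with the global edge orientation flipped."""
        return BipartiteGraph(
            id=self.id,
            set_a=self.set_a,
            set_b=self.set_b,
            edges=frozenset((v, u) for u, v in self.edges),
        )

    def relabel(self, mapping: Mapping[str, str]) -> "BipartiteGraph":
        m = lambda u: str(mapping.get(u, u))  # noqa: E731
        return BipartiteGraph(
            id=self.id,
            set_a=tuple(m(u) for u in self.set_a),
            set_b=tuple(m(u) for u in self.set_b),
            edges=frozenset((m(u), m(v)) for u, v in self.edges),
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.set_a, bipartite=0)
        g.add_nodes_from(self.set_b, bipartite=1)
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass
class NetworkRecord:
    """A bipartite network plus its grouping metadata.

    ``publication_id`` groups networks created by the same set of
    researchers; ``domain`` and ``subgroup`` mirror the coarse and fine
    thematic groupings (e.g. species_interaction / plant_pollinator).
    """

    graph: BipartiteGraph
    domain: str
    subgroup: str
    publication_id: str

    def __post_init__(self) -> None:
        for name in ("domain", "subgroup", "publication_id"):
            if not getattr(self, name):
                raise ValidationError(
                    f"{self.graph.id}: metadata field {name!r} must be non-empty"
                )

    @property
    def id(self) -> str:
        return self.graph.id


class MetadataRow(NamedTuple):
    network_id: str
    domain: str
    subgroup: str
    publication_id: str


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_ORIENTATIONS = ("cols_to_rows", "rows_to_cols")


def read_incidence_matrix(
    path: str | Path,
    id: str | None = None,
    orientation: str = "cols_to_rows",
) -> BipartiteGraph:
    """Read a labelled incidence-matrix CSV into a :class:`BipartiteGraph`.

    The first row holds column labels and the first column row labels; cells
    are numeric and binarized at > 0 (weighted interaction counts collapse
    to edge presence). ``orientation`` fixes the collection-wide edge
    direction: ``cols_to_rows`` orients every edge column-node -> row-node.
    """
    path = Path(path)
    if orientation not in _ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {_ORIENTATIONS}")
    net_id = id if id is not None else path.stem

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise ValidationError(f"{net_id}: empty incidence matrix in {path}")

    col_labels = [c.strip() for c in rows[0][1:]]
    row_labels = [r[0].strip() for r in rows[1:]]
    if len(set(col_labels)) != len(col_labels):
        raise ValidationError(f"{net_id}: duplicate column labels in {path}")
    if len(set(row_labels)) != len(row_labels):
        raise ValidationError(f"{net_id}: duplicate row labels in {path}")

    edges: set[tuple[str, str]] = set()
    for r_lab, row in zip(row_labels, rows[1:]):
        body = row[1:]
        if len(body) != len(col_labels):
            raise ValidationError(
                f"{net_id}: ragged row {r_lab!r} in {path}"
            )
        for c_lab, cell in zip(col_labels, body):
            try:
                value = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"{net_id}: non-numeric cell at row {r_lab!r}, "
                    f"column {c_lab!r}: {cell!r}"
                ) from exc
            if value > 0:
                if orientation == "cols_to_rows":
                    edges.add((c_lab, r_lab))
                else:
                    edges.add((r_lab, c_lab))
    if not edges:
        raise ValidationError(f"{net_id}: incidence matrix has no interactions")
    return BipartiteGraph(
        id=net_id,
        set_a=tuple(row_labels),
        set_b=tuple(col_labels),
        edges=frozenset(edges),
    )


def write_incidence_matrix(g: BipartiteGraph, path: str | Path) -> Path:
    """Write ``g`` as a labelled 0/1 incidence CSV (rows = set_a, cols = set_b).

    Round trip: reading the file back (with the matching orientation)
    reproduces the identical edge set and label order.
    """
    path = Path(path)
    present = g.edges
    cols_to_rows = not g._source_in_a
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([""] + list(g.set_b))
        for r in g.set_a:
            row: list[str] = [r]
            for c in g.set_b:
                edge = (c, r) if cols_to_rows else (r, c)
                row.append("1" if edge in present else "0")
            writer.writerow(row)
    return path


_EDGE_LIST_HEADERS = {("source", "target"), ("from", "to")}


def read_edge_list(path: str | Path, id: str | None = None) -> BipartiteGraph:
    """Read a two-column TSV edge list (source label, target label).

    Node sets are inferred from column membership: every source goes to one
    set, every target to the other. A label seen in both columns violates
    bipartiteness and is rejected. Duplicate rows deduplicate.
    """
    path = Path(path)
    net_id = id if id is not None else path.stem
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if any(c.strip() for c in r)]
    if rows and tuple(c.strip().lower() for c in rows[0][:2]) in _EDGE_LIST_HEADERS:
        rows = rows[1:]
    if not rows:
        raise ValidationError(f"{net_id}: empty edge list in {path}")

    sources: list[str] = []
    targets: list[str] = []
    edges: set[tuple[str, str]] = set()
    for r in rows:
        if len(r) < 2 or not r[0].strip() or not r[1].strip():
            raise ValidationError(f"{net_id}: malformed edge-list row {r!r}")
        u, v = r[0].strip(), r[1].strip()
        if u not in sources:
            sources.append(u)
        if v not in targets:
            targets.append(v)
        edges.add((u, v))
    both = set(sources) & set(targets)
    if both:
        raise ValidationError(
            f"{net_id}: labels appear as both source and target "
            f"(violates bipartiteness): {sorted(both)[:5]}"
        )
    # sources are the "from" set; store them as set_b to mirror the
    # cols_to_rows incidence convention (columns = sources).
    return BipartiteGraph(
        id=net_id,
        set_a=tuple(targets),
        set_b=tuple(sources),
        edges=frozenset(edges),
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def giant_component(g: BipartiteGraph) -> BipartiteGraph:
    """Induced subgraph on the largest weakly connected component.

    Ties between equal-size components break deterministically toward the
    component containing the lexicographically smallest node label.
    """
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    und.add_edges_from(g.edges)
    components = list(nx.connected_components(und))
    if len(components) == 1:
        return g
    max_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == max_size]
    best = min(tied, key=lambda c: min(c))
    set_a = tuple(u for u in g.set_a if u in best)
    set_b = tuple(u for u in g.set_b if u in best)
    edges = frozenset((u, v) for u, v in g.edges if u in best and v in best)
    return BipartiteGraph(id=g.id, set_a=set_a, set_b=set_b, edges=edges)


def filter_min_side(g: BipartiteGraph, k: int = 5) -> bool:
    """True iff each of the two node sets has at least ``k`` nodes."""
    if k < 1:
        raise ValidationError(f"min side k must be >= 1, got {k}")
    return len(g.set_a) >= k and len(g.set_b) >= k


# ---------------------------------------------------------------------------
# metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = ["network_id", "domain", "subgroup", "publication_id"]


def read_metadata(path: str | Path) -> list[MetadataRow]:
    """Read the per-network metadata CSV.

    Requires columns network_id, domain, subgroup, publication_id; network
    ids must be unique and every field non-empty. Ids without a matching
    network file are tolerated here and reconciled by the pipeline.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata {path}: missing columns {missing}")
    df = df[_META_COLUMNS]
    if df["network_id"].duplicated().any():
        dups = df.loc[df["network_id"].duplicated(), "network_id"].tolist()
        raise ValidationError(f"metadata {path}: duplicate network ids {dups[:5]}")
    rows: list[MetadataRow] = []
    for rec in df.itertuples(index=False):
        values = [getattr(rec, c) for c in _META_COLUMNS]
        if any(pd.isna(v) or not str(v).strip() for v in values):
            raise ValidationError(
                f"metadata {path}: empty field in row {tuple(values)}"
            )
        rows.append(MetadataRow(*(str(v).strip() for v in values)))
    return rows


def write_metadata(rows: Iterable[MetadataRow], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)
    return path


def attach_metadata(
    graphs: Sequence[BipartiteGraph], rows: Sequence[MetadataRow]
) -> list[NetworkRecord]:
    """Join loaded graphs with metadata rows on network id.

    Graphs without metadata and metadata without graphs are dropped with a
    logged warning; the caller decides whether the survivors suffice.
    """
    by_id = {r.network_id: r for r in rows}
    records: list[NetworkRecord] = []
    for g in graphs:
        row = by_id.pop(g.id, None)
        if row is None:
            logger.warning("network %s has no metadata row; dropped", g.id)
            continue
        records.append(
            NetworkRecord(
                graph=g,
                domain=row.domain,
                subgroup=row.subgroup,
                publication_id=row.publication_id,
            )
        )
    for orphan in by_id:
        logger.warning("metadata row %s matches no loaded network; ignored", orphan)
    return records
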
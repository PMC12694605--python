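"""Heterogeneous knowledge-graph data model, I/O and adjacency construction.

The graph links four node types — Disease, Vaccine, Adjuvant, Platform — by
typed edges (vaccine-targets-disease, vaccine-uses-adjuvant,
vaccine-on-platform).  Adjuvants are anchored by Vaccine Ontology (VO)
identifiers; diseases by their curated name strings.  Node identifiers are
opaque: no ontology reasoning happens here.

For propagation the graph is treated as a single undirected graph; edge types
are retained as metadata only.  Matrix views use a stable lexicographic node
ordering by ``(node_type, node_id)`` so that every matrix in the pipeline is
bit-reproducible from the input files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

NODE_TYPES = ("Adjuvant", "Disease", "Platform", "Vaccine")


class GraphParseError(ValueError):
    """Raised when a graph file violates the schema (bad type, dangling edge...)."""


@dataclass(frozen=True)
class Node:
    node_id: str
    node_type: str
    text: str = ""

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise GraphParseError(
                f"unknown node_type {self.node_type!r} for node {self.node_id!r}; "
                f"expected one of {NODE_TYPES}"
            )


@dataclass(frozen=True)
class Edge:
    src: str
    edge_type: str
    dst: str


class HeteroGraph:
    """Typed nodes and edges plus a deterministic matrix ordering.

    Nodes are ordered lexicographically by ``(node_type, node_id)``; the
    ordering is exposed through :attr:`node_ids` and :meth:`index_of` and is
    the row/column order of every matrix view.
    """

    def __init__(self, nodes: Iterable[Node], edges: Iterable[Edge]):
        nodes = list(nodes)
        ids = [n.node_id for n in nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GraphParseError(f"duplicate node ids: {dupes}")
        self._nodes = sorted(nodes, key=lambda n: (n.node_type, n.node_id))
        self._index = {n.node_id: i for i, n in enumerate(self._nodes)}
        self._edges = []
        for e in edges:
            for endpoint in (e.src, e.dst):
                if endpoint not in self._index:
                    raise GraphParseError(
                        f"edge ({e.src!r} -[{e.edge_type}]-> {e.dst!r}) references "
                        f"missing node {endpoint!r}"
                    )
            if e.src == e.dst:
                raise GraphParseError(f"self-edge on {e.src!r} not allowed in input")
            self._edges.append(e)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes)

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def node_ids(self) -> list[str]:
        return [n.node_id for n in self._nodes]

    def index_of(self, node_id: str) -> int:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"node {node_id!r} not in graph") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def node(self, node_id: str) -> Node:
        return self._nodes[self.index_of(node_id)]

    def nodes_of_type(self, node_type: str) -> list[Node]:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node_type {node_type!r}")
        return [n for n in self._nodes if n.node_type == node_type]

    def ids_of_type(self, node_type: str) -> list[str]:
        return [n.node_id for n in self.nodes_of_type(node_type)]

    # -- matrix views ------------------------------------------------------
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric binary adjacency A over the stable ordering (no self-loops)."""
        n = self.n_nodes
        if not self._edges:
            return sp.csr_matrix((n, n))
        rows, cols = [], []
        for e in self._edges:
            i, j = self._index[e.src], self._index[e.dst]
            rows += [i, j]
            cols += [j, i]
        a = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        a.data[:] = 1.0  # collapse parallel edges
        return a

    def normalized_adjacency(self) -> sp.csr_matrix:
        """Row-stochastic Â = D⁻¹(A + I) with self-loops.

        Every row sums to one; an isolated node's row is its own self-loop.
        """
        if self.n_nodes == 0:
            raise ValueError("cannot normalize the adjacency of an empty graph")
        a = self.adjacency() + sp.identity(self.n_nodes, format="csr")
        inv_deg = 1.0 / np.asarray(a.sum(axis=1)).ravel()
        return sp.diags(inv_deg) @ a


# ---------------------------------------------------------------------------
# TSV / JSON I/O
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GraphParseError(f"{path}: missing columns {missing}")
    return df


def read_graph(edge_path: str | Path, node_path: str | Path) -> HeteroGraph:
    """Read a graph from ``edges.tsv`` (src, edge_type, dst) and ``nodes.tsv``
    (node_id, node_type, text).

    Raises :class:`GraphParseError` with the offending line number for an
    unknown node type, and with the missing id for a dangling edge endpoint.
    """
    ndf = _read_tsv(node_path, ("node_id", "node_type", "text"))
    nodes = []
    for line_no, row in enumerate(ndf.itertuples(index=False), start=2):
        if row.node_type not in NODE_TYPES:
            raise GraphParseError(
                f"{node_path}:{line_no}: unknown node_type {row.node_type!r} "
                f"(expected one of {NODE_TYPES})"
            )
        nodes.append(Node(row.node_id, row.node_type, row.text))
    edf = _read_tsv(edge_path, ("src", "edge_type", "dst"))
    edges = [Edge(r.src, r.edge_type, r.dst) for r in edf.itertuples(index=False)]
    return HeteroGraph(nodes, edges)


def write_graph(g: HeteroGraph, edge_path: str | Path, node_path: str | Path) -> None:
    pd.DataFrame(
        [(n.node_id, n.node_type, n.text) for n in g.nodes],
        columns=["node_id", "node_type", "text"],
    ).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(
        [(e.src, e.edge_type, e.dst) for e in g.edges],
        columns=["src", "edge_type", "dst"],
    ).to_csv(edge_path, sep="\t", index=False)


def graph_to_json(g: HeteroGraph) -> str:
    """Single-file JSON serialization (used for fixtures)."""
    return json.dumps(
        {
            "nodes": [
                {"node_id": n.node_id, "node_type": n.node_type, "text": n.text}
                for n in g.nodes
            ],
            "edges": [
                {"src": e.src, "edge_type": e.edge_type, "dst": e.dst}
                for e in g.edges
            ],
        },
        indent=1,
    )


def graph_from_json(text: str) -> HeteroGraph:
    obj = json.loads(text)
    return HeteroGraph(
        (Node(n["node_id"], n["node_type"], n.get("text", "")) for n in obj["nodes"]),
        (Edge(e["src"], e["edge_type"], e["dst"]) for e in obj["edges"]),
    )


# ---------------------------------------------------------------------------
# Queries with graded gains
# ---------------------------------------------------------------------------

@dataclass
class QuerySet:
    """Per-disease candidate lists with graded gains.

    ``candidates`` is the shared candidate set — every Adjuvant node, in the
    stable graph order.  ``gains[d][i]`` is 2 for a known (d, candidate i)
    positive, 1 when candidate i shares a functional class with any positive
    of d, and 0 otherwise.
    """

    candidates: list[str]
    gains: dict[str, np.ndarray]
    positives: dict[str, frozenset] = field(default_factory=dict)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.gains)


def read_pairs(path: str | Path, cols: tuple[str, str]) -> pd.DataFrame:
    return _read_tsv(path, cols)


def query_set(
    g: HeteroGraph,
    positives: pd.DataFrame,
    classes: pd.DataFrame,
) -> QuerySet:
    """Build graded-gain queries from a positive-pair table and a class table.

    ``positives`` has columns (disease_id, adjuvant_id); ``classes`` has one
    row per class membership (adjuvant_id, class_label).  Diseases with zero
    positives are excluded (NDCG is undefined when the ideal gain is zero)
    with a logged warning.  Gains depend only on table *contents*: row order
    never matters.
    """
    candidates = g.ids_of_type("Adjuvant")
    cand_index = {a: i for i, a in enumerate(candidates)}

    bad = sorted(set(positives["adjuvant_id"]) - set(cand_index))
    if bad:
        raise GraphParseError(f"positive pairs reference unknown adjuvants: {bad}")

    classes_of: dict[str, set[str]] = {}
    for r in classes.itertuples(index=False):
        classes_of.setdefault(r.adjuvant_id, set()).add(r.class_label)

    pos_of: dict[str, set[str]] = {}
    for r in positives.itertuples(index=False):
        pos_of.setdefault(r.disease_id, set()).add(r.adjuvant_id)

    disease_ids = [n.node_id for n in g.nodes_of_type("Disease")]
    gains: dict[str, np.ndarray] = {}
    pos_out: dict[str, frozenset] = {}
    for d in disease_ids:
        pos = pos_of.get(d, set())
        if not pos:
            logger.warning("disease %r has no positives; excluded from queries", d)
            continue
        pos_classes: set[str] = set()
        for a in pos:
            pos_classes |= classes_of.get(a, set())
        g_vec = np.zeros(len(candidates), dtype=np.int64)
        for i, a in enumerate(candidates):
            if a in pos:
                g_vec[i] = 2
            elif classes_of.get(a, set()) & pos_classes:
                g_vec[i] = 1
        gains[d] = g_vec
        pos_out[d] = frozenset(pos)
    return QuerySet(candidates=candidates, gains=gains, positives=pos_out)
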
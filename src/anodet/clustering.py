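"""Match-count similarity, threshold graph, grouping and anomaly flagging.

Two students' similarity is the number of repetitions ``z`` (out of
``q``) in which their health indexes are equal in *at least one* of the
``p`` hash tables — an integer in ``[0, q]``.  Students with similarity
``>= T`` are deemed similar; groups are the connected components of the
resulting threshold graph; a student with no similar peer (a degree-zero
vertex) is flagged as an anomaly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import ValidationError
from .lsh import IndexTable

__all__ = [
    "SimilarityGraph",
    "AnomalyReport",
    "pair_similarity",
    "similarity_matrix",
    "threshold_graph",
    "cluster_students",
    "detect_anomalies",
]


def pair_similarity(index_i, index_j, p: int | None = None) -> int:
    """Match count between two students' index vectors.

    ``index_i`` and ``index_j`` are p-lists of q-lists of integers (one
    q-vector per hash table); a flat q-list is accepted as the p=1 case.
    Returns the number of repetition slots ``z`` whose indexes are equal
    in at least one table.
    """
    index_i = _as_tables(index_i)
    index_j = _as_tables(index_j)
    if p is not None and (len(index_i) != p or len(index_j) != p):
        raise ValidationError(
            f"expected {p} tables, got {len(index_i)} and {len(index_j)}"
        )
    if len(index_i) != len(index_j):
        raise ValidationError(
            f"students hashed with different table counts: "
            f"{len(index_i)} vs {len(index_j)}"
        )
    lengths = {len(row) for row in index_i} | {len(row) for row in index_j}
    if len(lengths) != 1:
        raise ValidationError(f"inconsistent repetition counts: {sorted(lengths)}")
    (q,) = lengths
    return sum(
        1
        for z in range(q)
        if any(ti[z] == tj[z] for ti, tj in zip(index_i, index_j))
    )


def _as_tables(index) -> list[list[int]]:
    index = list(index)
    if index and not isinstance(index[0], (list, tuple)):
        return [list(index)]
    return [list(row) for row in index]


@dataclass
class SimilarityGraph:
    """All-pairs match-count similarities, optionally thresholded.

    ``sim`` is a symmetric integer matrix with diagonal ``q`` (a student
    trivially matches itself in every repetition; the diagonal is never
    used for anomaly decisions).  After thresholding, ``graph`` holds the
    adjacency: an edge (i, j), i != j, wherever ``sim[i, j] >= T``.
    """

    student_ids: list[str]
    sim: np.ndarray
    q: int
    T: int | None = None
    graph: nx.Graph | None = field(default=None, repr=False)

    def __post_init__(self):
        self.sim = np.asarray(self.sim)
        n = len(self.student_ids)
        if self.sim.shape != (n, n):
            raise ValidationError(
                f"similarity matrix shape {self.sim.shape} != ({n}, {n})"
            )
        if not np.issubdtype(self.sim.dtype, np.integer):
            raise ValidationError("similarity entries must be integers")
        if (self.sim < 0).any() or (self.sim > self.q).any():
            raise ValidationError(f"similarities must lie in [0, q={self.q}]")
        if not np.array_equal(self.sim, self.sim.T):
            raise ValidationError("similarity matrix must be symmetric")
        if not (np.diag(self.sim) == self.q).all():
            raise ValidationError("self-similarity must equal q")

    @property
    def n_students(self) -> int:
        return len(self.student_ids)


@dataclass
class AnomalyReport:
    """Groups, flagged anomalies and per-student neighbor counts."""

    student_ids: list[str]
    groups: list[list[str]]
    anomalies: list[str]
    neighbor_counts: dict[str, int]
    T: int
    p: int | None = None
    q: int | None = None
    seed: int | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {"T": self.T, "p": self.p, "q": self.q, "seed": self.seed},
            "groups": self.groups,
            "anomalies": self.anomalies,
            "neighbor_counts": self.neighbor_counts,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def similarity_matrix(index: IndexTable) -> SimilarityGraph:
    """Compute all N(N-1)/2 pairwise match counts from an index table.

    Grouping by index value within each (table, repetition) slot makes
    this O(p*q*N^2) on small dense cohorts without bignum comparisons in
    the inner loop.
    """
    n = index.n_students
    matched = np.zeros((index.q, n, n), dtype=bool)
    for t in range(index.p):
        for z in range(index.q):
            values = [index.pi[t][i][z] for i in range(n)]
            codes_map: dict[int, int] = {}
            codes = np.empty(n, dtype=np.int64)
            for i, v in enumerate(values):
                codes[i] = codes_map.setdefault(v, len(codes_map))
            matched[z] |= codes[:, None] == codes[None, :]
    sim = matched.sum(axis=0).astype(np.int64)
    np.fill_diagonal(sim, index.q)
    return SimilarityGraph(student_ids=list(index.student_ids), sim=sim, q=index.q)


def threshold_graph(graph: SimilarityGraph, T: int) -> SimilarityGraph:
    """Fill the adjacency at level ``T``: edge iff Sim >= T, i != j."""
    if not isinstance(T, (int, np.integer)) or not 1 <= T <= graph.q:
        raise ValidationError(f"T must satisfy 1 <= T <= q={graph.q}, got {T!r}")
    g = nx.Graph()
    g.add_nodes_from(graph.student_ids)
    ii, jj = np.nonzero(np.triu(graph.sim >= T, k=1))
    g.add_edges_from(
        (graph.student_ids[i], graph.student_ids[j]) for i, j in zip(ii, jj)
    )
    return SimilarityGraph(
        student_ids=list(graph.student_ids),
        sim=graph.sim,
        q=graph.q,
        T=int(T),
        graph=g,
    )


def cluster_students(graph: SimilarityGraph) -> list[list[str]]:
    """Partition students into groups: connected components of the
    threshold graph, each sorted and listed by smallest member index."""
    if graph.graph is None:
        raise ValidationError("threshold the graph before clustering")
    order = {sid: i for i, sid in enumerate(graph.student_ids)}
    components = [
        sorted(comp, key=order.__getitem__)
        for comp in nx.connected_components(graph.graph)
    ]
    components.sort(key=lambda comp: order[comp[0]])
    return components


def detect_anomalies(
    graph: SimilarityGraph,
    p: int | None = None,
    seed: int | None = None,
) -> AnomalyReport:
    """Flag every degree-zero student in the threshold graph as an anomaly."""
    if graph.graph is None:
        raise ValidationError("threshold the graph before detecting anomalies")
    counts = {sid: graph.graph.degree(sid) for sid in graph.student_ids}
    anomalies = [sid for sid in graph.student_ids if counts[sid] == 0]
    return AnomalyReport(
        student_ids=list(graph.student_ids),
        groups=cluster_students(graph),
        anomalies=anomalies,
        neighbor_counts=counts,
        T=graph.T,
        p=p,
        q=graph.q,
        seed=seed,
    )
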
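"""Graph-theory metrics for binary and weighted connectomes.

Integration is quantified through shortest paths: an edge of weight w
has length 1/w (one hop in a binary network), so strong connections are
short.  Global efficiency is the average inverse shortest-path length
over ordered node pairs, with disconnected pairs contributing zero.

Segregation is quantified per node: nodal efficiency is the global
efficiency of the subgraph induced by the node's neighbours (the node
itself excluded), and the clustering coefficient counts (binary) or
weighs (Onnela geometric-mean formula on max-normalised weights) the
triangles closed around the node.  Degree and strength count and sum a
node's connections.  Global summaries average the nodal values over all
nodes of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectome import Connectome

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "shortest_path_matrix",
    "global_efficiency",
    "nodal_efficiency",
    "closeness_efficiency",
    "clustering_coefficient",
    "degrees",
    "strengths",
    "summarize",
    "metrics_table",
]


@dataclass
class NodalMetrics:
    """Per-node metric vectors, aligned with the connectome's node order."""

    degree: np.ndarray
    strength: np.ndarray
    nodal_efficiency: np.ndarray
    clustering: np.ndarray

    def to_frame(self, labels: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_label": labels,
                "degree": self.degree,
                "strength": self.strength,
                "nodal_efficiency": self.nodal_efficiency,
                "clustering": self.clustering,
            }
        )


@dataclass
class GlobalMetrics:
    """Whole-network summaries (nodal averages plus global efficiency)."""

    avg_degree: float
    avg_strength: float
    global_efficiency: float
    local_efficiency: float
    avg_clustering: float

    def as_dict(self) -> dict[str, float]:
        return {
            "avg_degree": self.avg_degree,
            "avg_strength": self.avg_strength,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
            "avg_clustering": self.avg_clustering,
        }


def _weights(conn: Connectome | np.ndarray) -> np.ndarray:
    return conn.weights if isinstance(conn, Connectome) else np.asarray(conn, dtype=float)


def shortest_path_matrix(conn: Connectome | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances over edge lengths 1/weight.

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    w = _weights(conn)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return _csgraph_shortest_path(lengths, method="D", directed=False)


def _efficiency_from_weights(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path_matrix(w)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def global_efficiency(conn: Connectome | np.ndarray) -> float:
    """Mean of 1/d(i, j) over ordered pairs i != j (1/inf = 0)."""
    w = _weights(conn)
    if w.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _efficiency_from_weights(w)


def nodal_efficiency(conn: Connectome | np.ndarray, node: int) -> float:
    """Efficiency of the subnetwork formed by the node's neighbours.

    The node itself is excluded from its neighbour subgraph; a node with
    fewer than two neighbours has no subnetwork and scores 0.
    """
    w = _weights(conn)
    n = w.shape[0]
    if not 0 <= node < n:
        raise IndexError(f"node {node} outside 0..{n - 1}")
    neighbours = np.flatnonzero(w[node] > 0)
    if neighbours.size < 2:
        return 0.0
    sub = w[np.ix_(neighbours, neighbours)]
    return _efficiency_from_weights(sub)


def closeness_efficiency(conn: Connectome | np.ndarray, node: int) -> float:
    """Average inverse shortest-path distance from the node to all others.

    An alternative, closeness-style reading of per-node efficiency; kept
    as a non-default option (:func:`nodal_efficiency` is the default).
    """
    w = _weights(conn)
    n = w.shape[0]
    if not 0 <= node < n:
        raise IndexError(f"node {node} outside 0..{n - 1}")
    if n < 2:
        return 0.0
    d = shortest_path_matrix(w)[node]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    inv[node] = 0.0
    return float(inv.sum() / (n - 1))


def clustering_coefficient(conn: Connectome | np.ndarray, node: int) -> float:
    """Triangle closure around a node.

    Binary: fraction of neighbour pairs that are themselves connected.
    Weighted: Onnela geometric-mean triangle intensity on weights
    normalised by the network maximum; identical to the binary value
    when all edge weights are equal.  Degree < 2 scores 0.
    """
    w = _weights(conn)
    n = w.shape[0]
    if not 0 <= node < n:
        raise IndexError(f"node {node} outside 0..{n - 1}")
    k = int(np.count_nonzero(w[node]))
    if k < 2:
        return 0.0
    is_binary = np.isin(w, (0.0, 1.0)).all()
    if is_binary:
        nb = np.flatnonzero(w[node] > 0)
        sub = w[np.ix_(nb, nb)]
        triangles = sub.sum() / 2.0
        return float(triangles / (k * (k - 1) / 2.0))
    w_hat = np.cbrt(w / w.max())
    # sum over ordered neighbour pairs (j, h) of (w_ij w_ih w_jh)^(1/3)
    intensity = float(w_hat[node] @ w_hat @ w_hat[node])
    return intensity / (k * (k - 1))


def degrees(conn: Connectome | np.ndarray) -> np.ndarray:
    """Number of connections per node (any nonzero weight counts)."""
    return np.count_nonzero(_weights(conn), axis=1)


def strengths(conn: Connectome | np.ndarray) -> np.ndarray:
    """Sum of connection weights per node (row sums)."""
    return _weights(conn).sum(axis=1)


def summarize(conn: Connectome | np.ndarray) -> tuple[NodalMetrics, GlobalMetrics]:
    """All nodal metrics plus their whole-network averages.

    ``local_efficiency`` and ``avg_clustering`` are the means of the
    nodal efficiency and clustering over every node; ``global_efficiency``
    is computed once on the full network.
    """
    w = _weights(conn)
    n = w.shape[0]
    nodal = NodalMetrics(
        degree=degrees(w),
        strength=strengths(w),
        nodal_efficiency=np.array([nodal_efficiency(w, i) for i in range(n)]),
        clustering=np.array([clustering_coefficient(w, i) for i in range(n)]),
    )
    glob = GlobalMetrics(
        avg_degree=float(nodal.degree.mean()),
        avg_strength=float(nodal.strength.mean()),
        global_efficiency=global_efficiency(w),
        local_efficiency=float(nodal.nodal_efficiency.mean()),
        avg_clustering=float(nodal.clustering.mean()),
    )
    return nodal, glob


def metrics_table(conn: Connectome, subject_id: str | None = None) -> pd.DataFrame:
    """Tidy per-subject metric table: one row per (scope, node, metric)."""
    nodal, glob = summarize(conn)
    sid = subject_id or conn.subject_id or ""
    rows = [
        {
            "subject_id": sid,
            "connectome_kind": conn.kind,
            "scope": "global",
            "node_label": "",
            "metric_name": name,
            "value": value,
        }
        for name, value in glob.as_dict().items()
    ]
    metric_vectors = {
        "degree": nodal.degree,
        "strength": nodal.strength,
        "nodal_efficiency": nodal.nodal_efficiency,
        "clustering": nodal.clustering,
    }
    for name, vec in metric_vectors.items():
        for node, value in zip(conn.nodes, vec):
            rows.append(
                {
                    "subject_id": sid,
                    "connectome_kind": conn.kind,
                    "scope": "node",
                    "node_label": node.label,
                    "metric_name": name,
                    "value": float(value),
                }
            )
    return pd.DataFrame(rows)
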
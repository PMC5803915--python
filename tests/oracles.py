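"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths under test: distances come from
a Floyd-Warshall relaxation written here, graph metrics from explicit
set/loop definitions or from networkx, and rank statistics from direct
rank-then-formula evaluation.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def floyd_warshall_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths over lengths 1/weight by triple-loop relaxation."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_oracle(weights: np.ndarray) -> float:
    """Mean inverse distance over ordered pairs, from the Floyd-Warshall oracle."""
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall_distances(weights)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_efficiency_oracle(weights: np.ndarray, node: int) -> float:
    """Materialise the neighbour subgraph and apply the efficiency oracle."""
    neighbours = [j for j in range(weights.shape[0]) if weights[node, j] > 0]
    if len(neighbours) < 2:
        return 0.0
    sub = weights[np.ix_(neighbours, neighbours)]
    return efficiency_oracle(sub)


def binary_clustering_oracle(weights: np.ndarray, node: int) -> float:
    """Closed-triangle count over neighbour pairs, by explicit enumeration."""
    neighbours = [j for j in range(weights.shape[0]) if weights[node, j] > 0]
    k = len(neighbours)
    if k < 2:
        return 0.0
    closed = sum(
        1 for a, b in itertools.combinations(neighbours, 2) if weights[a, b] > 0
    )
    return closed / (k * (k - 1) / 2)


def weighted_clustering_oracle(weights: np.ndarray, node: int) -> float:
    """Onnela weighted clustering via networkx (max-normalised weights)."""
    g = nx.from_numpy_array(weights)
    return nx.clustering(g, nodes=node, weight="weight")


def structural_accumulation_oracle(streamlines, n, volumes, kind):
    """Per-pair accumulation of streamline records into a weight matrix.

    ``streamlines`` is a list of (i, j, length, fa) tuples.
    """
    from collections import defaultdict

    per_pair = defaultdict(list)
    for i, j, length, fa in streamlines:
        if i == j:
            continue
        per_pair[frozenset((i, j))].append((length, fa))
    w = np.zeros((n, n))
    for pair, items in per_pair.items():
        i, j = sorted(pair)
        if kind == "binary":
            value = 1.0
        elif kind == "fa_weighted":
            value = float(np.mean([fa for _, fa in items]))
        else:
            value = sum(1.0 / length for length, _ in items) / (volumes[i] * volumes[j])
        w[i, j] = w[j, i] = value
    return w


def pcorr_regression_oracle(data: np.ndarray) -> np.ndarray:
    """Partial correlations via residualisation on all remaining series."""
    n, t = data.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            others = [k for k in range(n) if k not in (i, j)]
            X = np.column_stack([np.ones(t)] + [data[k] for k in others])
            ri = data[i] - X @ np.linalg.lstsq(X, data[i], rcond=None)[0]
            rj = data[j] - X @ np.linalg.lstsq(X, data[j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def spearman_oracle(x, y) -> float:
    """Rank both vectors (midranks) and take the Pearson correlation."""
    from scipy.stats import rankdata

    return float(np.corrcoef(rankdata(x), rankdata(y))[0, 1])


def kw_h_oracle(a, b) -> float:
    """Kruskal-Wallis H by direct rank-sum formula with tie correction."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = pooled.size
    h = (
        12.0 / (n * (n + 1)) * sum(
            ranks[idx].sum() ** 2 / len(idx)
            for idx in (np.arange(len(a)), np.arange(len(a), n))
        )
        - 3 * (n + 1)
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie else 0.0


def random_symmetric_graph(n, rng, weighted=False, density=0.5):
    """Random symmetric zero-diagonal adjacency matrix."""
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < density
    vals = rng.uniform(0.1, 2.0, iu[0].size) if weighted else np.ones(iu[0].size)
    w[iu] = present * vals
    return w + w.T
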
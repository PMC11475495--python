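"""Patient similarity graph from thresholded Pearson correlation.

Nodes are samples; an undirected edge joins two samples whose Pearson
correlation across the (z-scored) feature matrix is at least the threshold
(default 0.7, inclusive, positive correlations only).  Self-loops default ON
so every node's own features enter its attention aggregation even when the
node is otherwise isolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import ConfigurationError, UndefinedCorrelationError


@dataclass(frozen=True)
class SampleGraph:
    """Undirected graph over samples; ``edges`` holds i < j pairs (no self-loops)."""

    n_nodes: int
    edges: frozenset
    correlation_threshold: float = 0.7
    self_loops: bool = True
    correlation_method: str = "pearson"
    edge_weights: dict = field(default_factory=dict, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix (symmetric; diagonal set when self_loops)."""
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = True
        if self.self_loops:
            np.fill_diagonal(adj, True)
        return adj

    def neighbors(self, i: int) -> np.ndarray:
        return np.nonzero(self.adjacency()[i])[0]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            (i, j, self.edge_weights.get((i, j), 1.0)) for i, j in self.edges
        )
        if self.self_loops:
            g.add_edges_from((i, i) for i in range(self.n_nodes))
        return g


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ConfigurationError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def build_sample_graph(
    feature_matrix: np.ndarray,
    threshold: float = 0.7,
    self_loops: bool = True,
    standardize: bool = True,
) -> SampleGraph:
    """Threshold the sample-sample correlation matrix into a graph.

    Features are z-scored per column first (disable with
    ``standardize=False`` when the matrix is already standardized).  An edge
    (i, j), i != j, exists iff corr(row_i, row_j) >= threshold; constant rows
    have undefined correlations and receive no edges.
    """
    if not -1 < threshold <= 1:
        raise ConfigurationError("threshold must lie in (-1, 1]")
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigurationError("need a 2-d matrix with at least 2 samples")
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    row_sd = X.std(axis=1)
    constant = row_sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.where(np.isfinite(corr), corr, -np.inf)  # constant rows: no edges

    iu, ju = np.nonzero(np.triu(corr >= threshold, k=1))
    keep = ~constant[iu] & ~constant[ju]
    edges = frozenset((int(i), int(j)) for i, j in zip(iu[keep], ju[keep]))
    weights = {(int(i), int(j)): float(corr[i, j]) for i, j in zip(iu[keep], ju[keep])}
    return SampleGraph(
        n_nodes=X.shape[0],
        edges=edges,
        correlation_threshold=threshold,
        self_loops=self_loops,
        edge_weights=weights,
    )
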
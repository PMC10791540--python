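"""Cluster-level fuzzy recurrence networks and their graph properties.

Cluster-to-cluster similarity grades are inferred from the FCM membership
matrix by max-min composition over the phase-space points (grades below a
floor ``beta`` are pruned first).  An alpha-cut crisps the similarity relation
into an unweighted graph whose characteristic path length and average
clustering coefficient are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import InputError
from .recurrence import FuzzyPartition

__all__ = [
    "ClusterSimilarity",
    "RecurrenceNetwork",
    "GraphProperties",
    "cluster_similarity",
    "alpha_cut_adjacency",
    "graph_properties",
]


@dataclass
class ClusterSimilarity:
    """Symmetric c x c matrix of cluster-pair grades with unit diagonal."""

    S: np.ndarray
    beta: float

    @property
    def c(self) -> int:
        return self.S.shape[0]


@dataclass
class RecurrenceNetwork:
    """Unweighted alpha-cut network: symmetric binary adjacency, zero diagonal."""

    A: np.ndarray
    alpha: float

    @property
    def c(self) -> int:
        return self.A.shape[0]

    def edge_count(self) -> int:
        return int(self.A.sum()) // 2


@dataclass
class GraphProperties:
    characteristic_path_length: float
    average_clustering_coefficient: float


def cluster_similarity(partition: FuzzyPartition, beta: float = 0.08) -> ClusterSimilarity:
    """Cluster-pair similarity by max-min composition over points.

    Point-to-cluster grades below ``beta`` are floored to zero before the
    composition ``S(k, q) = max_i min(mu_ik, mu_iq)``; the diagonal is 1 by
    reflexivity.
    """
    if not 0.0 <= beta <= 1.0:
        raise InputError("beta must lie in [0, 1]")
    U = np.where(partition.memberships >= beta, partition.memberships, 0.0)
    # S[k, q] = max over points i of min(U[i, k], U[i, q])
    S = np.minimum(U[:, :, None], U[:, None, :]).max(axis=0)
    np.fill_diagonal(S, 1.0)
    return ClusterSimilarity(S=S, beta=beta)


def alpha_cut_adjacency(S: ClusterSimilarity, alpha: float = 0.4) -> RecurrenceNetwork:
    """Crisp the similarity relation at level ``alpha`` and drop self-loops."""
    if not 0.0 <= alpha <= 1.0:
        raise InputError("alpha must lie in [0, 1]")
    G = (S.S >= alpha).astype(np.int8)
    A = G - np.eye(S.c, dtype=np.int8)
    return RecurrenceNetwork(A=A, alpha=alpha)


def graph_properties(net: RecurrenceNetwork) -> GraphProperties:
    """Characteristic path length and average clustering coefficient.

    Path length averages shortest-path distances over ordered node pairs with
    finite distance (self-pairs excluded; 0 when the graph has no edges).
    Clustering per node is ``2 * triangles / (deg * (deg - 1))`` with
    degree < 2 contributing 0, averaged over all nodes.
    """
    g = nx.from_numpy_array(np.asarray(net.A))
    distances = [
        d
        for _, targets in nx.all_pairs_shortest_path_length(g)
        for d in targets.values()
        if d > 0
    ]
    cpl = float(np.mean(distances)) if distances else 0.0
    acc = float(nx.average_clustering(g)) if g.number_of_nodes() else 0.0
    return GraphProperties(characteristic_path_length=cpl,
                           average_clustering_coefficient=acc)
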
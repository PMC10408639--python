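"""Newman modularity and Louvain community detection for weighted graphs.

Modularity of a partition measures the excess within-community edge
weight over a degree-preserving random expectation:

    Q = (1/2m) * sum_ij [ A_ij - k_i k_j / (2m) ] * delta(c_i, c_j)

summed over ordered node pairs (A_ii = 0 at the term level), where A_ij
is the link weight, k_i the weighted degree, m the sum of all link
weights and delta the Kronecker delta on community labels.

The Louvain method greedily maximizes Q in two repeating phases: local
node moves from singleton communities, then aggregation of communities
into super-nodes (with self-loops carrying internal weight).  Iteration
stops when no move improves modularity, so the number of communities —
interpreted downstream as the number of topics — is emergent, never
user-fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .network import CooccurrenceNetwork

__all__ = [
    "CommunityPartition",
    "modularity",
    "louvain_partition",
    "LouvainCommunities",
]


@dataclass
class CommunityPartition:
    """A node→community assignment with its modularity score."""

    assignment: dict[str, int]
    modularity: float
    n_communities: int
    levels: int = 1
    seed: int = 0
    tolerance: float = 1e-12

    def communities(self) -> dict[int, list[str]]:
        """Community id → sorted member list."""
        out: dict[int, list[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, []).append(node)
        for members in out.values():
            members.sort()
        return out


def _adjacency(network) -> dict:
    """Adjacency dict-of-dicts from a CooccurrenceNetwork or nx.Graph."""
    g = network.graph if isinstance(network, CooccurrenceNetwork) else network
    adj: dict = {v: {} for v in g.nodes}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        if u == v:
            adj[u][u] = adj[u].get(u, 0.0) + 2.0 * w
        else:
            adj[u][v] = w
            adj[v][u] = w
    return adj


def _total_weight(adj: dict) -> float:
    # self-loops stored as 2*w contribute w to m
    return sum(sum(nbrs.values()) for nbrs in adj.values()) / 2.0


def modularity(network, partition) -> float:
    """Evaluate Q for a partition of the network's nodes.

    ``partition`` may be a :class:`CommunityPartition` or a plain
    node→community mapping.  Every node must be assigned; a graph with
    zero total weight has no defined modularity.
    """
    assignment = (
        partition.assignment
        if isinstance(partition, CommunityPartition)
        else dict(partition)
    )
    adj = _adjacency(network)
    missing = [v for v in adj if v not in assignment]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    m = _total_weight(adj)
    if m <= 0:
        raise ValueError("modularity undefined: total edge weight is zero")
    # Q = sum_c [ W_in(c)/(2m) - (tot_c/(2m))^2 ], W_in over ordered pairs
    w_in: dict[int, float] = {}
    tot: dict[int, float] = {}
    for u, nbrs in adj.items():
        cu = assignment[u]
        k_u = sum(nbrs.values())
        tot[cu] = tot.get(cu, 0.0) + k_u
        for v, w in nbrs.items():
            if assignment[v] == cu:
                w_in[cu] = w_in.get(cu, 0.0) + w  # ordered pairs: u→v and v→u
    two_m = 2.0 * m
    return sum(
        w_in.get(c, 0.0) / two_m - (tot.get(c, 0.0) / two_m) ** 2 for c in tot
    )


def _local_move_phase(
    adj: dict, order: list, tolerance: float
) -> tuple[dict, bool]:
    """One level's greedy node-moving sweep-until-stable.

    Nodes start in singleton communities (ids follow ``order``) and are
    repeatedly offered their best neighboring community; a move is taken
    only when its modularity gain exceeds ``tolerance``, ties broken by
    largest gain then smallest community id.
    """
    m = _total_weight(adj)
    node_comm = {v: i for i, v in enumerate(order)}
    degree = {v: sum(nbrs.values()) for v, nbrs in adj.items()}
    comm_tot = {node_comm[v]: degree[v] for v in order}
    improved_any = False

    while True:
        moved = False
        for v in order:
            k_v = degree[v]
            old_c = node_comm[v]
            # weight from v to each neighboring community (self-loop excluded)
            links: dict[int, float] = {}
            for u, w in adj[v].items():
                if u == v:
                    continue
                links[node_comm[u]] = links.get(node_comm[u], 0.0) + w
            # remove v from its community
            comm_tot[old_c] -= k_v
            base_gain = links.get(old_c, 0.0) / m - k_v * comm_tot[old_c] / (
                2.0 * m * m
            )
            # ascending id + strict > keeps the smallest community id
            # among tied best gains
            best_c, best_gain = old_c, base_gain
            for c in sorted(links):
                if c == old_c:
                    continue
                gain = links[c] / m - k_v * comm_tot.get(c, 0.0) / (2.0 * m * m)
                if gain > best_gain:
                    best_c, best_gain = c, gain
            if best_c != old_c and best_gain - base_gain > tolerance:
                node_comm[v] = best_c
                comm_tot[best_c] = comm_tot.get(best_c, 0.0) + k_v
                moved = True
                improved_any = True
            else:
                comm_tot[old_c] += k_v
        if not moved:
            break
    return node_comm, improved_any


def _aggregate(adj: dict, node_comm: dict) -> tuple[dict, dict]:
    """Collapse communities into super-nodes.

    Returns the aggregated adjacency (self-loops = 2x internal weight,
    matching the degree convention) and the node→super-node map.
    """
    comm_ids = sorted(set(node_comm.values()))
    relabel = {c: i for i, c in enumerate(comm_ids)}
    new_adj: dict = {relabel[c]: {} for c in comm_ids}
    for u, nbrs in adj.items():
        cu = relabel[node_comm[u]]
        for v, w in nbrs.items():
            cv = relabel[node_comm[v]]
            # adj already stores self-loops doubled; summing u→v over all
            # ordered pairs inside a community doubles internal weight,
            # which is exactly the self-loop convention we want
            new_adj[cu][cv] = new_adj[cu].get(cv, 0.0) + w
    return new_adj, {u: relabel[node_comm[u]] for u in adj}


def louvain_partition(
    network, seed: int = 0, tolerance: float = 1e-12
) -> CommunityPartition:
    """Two-phase Louvain modularity maximization.

    Phase 1 greedily moves nodes between communities; phase 2 aggregates
    communities into super-nodes and repeats.  A level that yields no
    modularity improvement terminates the iteration.  Node visiting order
    is the canonical sorted order shuffled with ``seed``, making runs
    reproducible; final community ids are contiguous integers numbered by
    first appearance in canonical node order.
    """
    adj = _adjacency(network)
    if _total_weight(adj) <= 0:
        raise ValueError("Louvain requires a network with at least one edge")
    rng = np.random.default_rng(seed)

    node_to_current = {v: v for v in adj}  # original node -> current super-node
    levels = 0
    while True:
        order = sorted(adj, key=str)
        idx = rng.permutation(len(order))
        order = [order[i] for i in idx]
        node_comm, improved = _local_move_phase(adj, order, tolerance)
        levels += 1
        if not improved:
            break
        adj, mapping = _aggregate(adj, node_comm)
        node_to_current = {
            v: mapping[node_comm_key]
            for v, node_comm_key in node_to_current.items()
        }
        if len(adj) == 1:
            break

    # contiguous ids by first appearance over sorted original nodes
    final: dict[str, int] = {}
    next_id = 0
    seen: dict = {}
    for v in sorted(node_to_current, key=str):
        c = node_to_current[v]
        if c not in seen:
            seen[c] = next_id
            next_id += 1
        final[v] = seen[c]
    part = CommunityPartition(
        assignment=final,
        modularity=0.0,
        n_communities=next_id,
        levels=levels,
        seed=seed,
        tolerance=tolerance,
    )
    part.modularity = modularity(network, part)
    return part


class LouvainCommunities(BaseEstimator, ClusterMixin):
    """Scikit-learn-style clusterer over a co-occurrence network.

    Parameters
    ----------
    seed : int, default=0
        Shuffle seed for the node visiting order (Louvain output is
        order-dependent; fixing the seed makes it reproducible).
    tolerance : float, default=1e-12
        Minimum modularity gain counted as an improvement.

    Attributes
    ----------
    partition_ : CommunityPartition
    labels_ : ndarray of community ids aligned with the fitted
        network's node order.
    modularity_ : float
    n_communities_ : int
    """

    def __init__(self, seed: int = 0, tolerance: float = 1e-12):
        self.seed = seed
        self.tolerance = tolerance

    def fit(self, X, y=None):
        self.partition_ = louvain_partition(X, seed=self.seed, tolerance=self.tolerance)
        nodes = X.nodes if isinstance(X, CooccurrenceNetwork) else list(X.nodes)
        self.labels_ = np.array([self.partition_.assignment[v] for v in nodes])
        self.modularity_ = self.partition_.modularity
        self.n_communities_ = self.partition_.n_communities
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
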
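"""Constrained-gene module discovery on protein interaction networks.

Gene-level selective-constraint statistics (signed Z scores of the deviation
between observed and expected rare missense variation) are transformed into
node prizes on an undirected protein-protein interaction graph, and the
maximum-profit connected subgraph is sought with a heuristic prize-collecting
Steiner tree (PCST) solver.  Genes whose constraint p-value passes a
Bonferroni-style threshold ``alpha`` carry positive weight ("signal" nodes);
all others are "null" and act as connection costs.

The exact PCST problem is NP-hard; the heuristic here follows the
signal/null contraction scheme validated for protein interaction networks:
connected components of the signal subgraph are contracted to supernodes,
cheapest connection costs between supernodes are found by multi-source
shortest paths (null nodes priced at ``-w``), a spanning forest of the
supernode metric is expanded back to graph nodes, and the resulting tree is
strong-pruned so no negative-profit subtree survives.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 5e-6

__all__ = [
    "DEFAULT_ALPHA",
    "SubnetworkSolution",
    "SubgraphStats",
    "constraint_p_from_z",
    "node_weight",
    "make_node_weights",
    "heuristic_pcst",
    "brute_force_pcst",
    "iterate_subnetworks",
    "subgraph_stats",
    "binomial_excess_test",
    "PCSTModuleFinder",
]


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def constraint_p_from_z(z):
    """Upper-tail standard normal p-value for a signed constraint Z score.

    Large positive Z means depletion of missense variation (constraint), so
    the upper tail makes small p correspond to strong constraint.  Values are
    clipped away from exact 0 so that ``log(p)`` stays finite.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("constraint Z scores must be finite")
    p = stats.norm.sf(z)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(p) if p.ndim == 0 else p


def node_weight(p_c, alpha: float = DEFAULT_ALPHA, base: float = math.e):
    """Node prize ``w = -log(p_c) + log(alpha)``.

    Positive exactly when ``p_c < alpha``; zero at ``p_c == alpha``.  The log
    base only rescales all weights uniformly (irrelevant at edge cost 0) and
    defaults to the natural log.
    """
    p_c = np.asarray(p_c, dtype=float)
    if np.any(p_c <= 0) or np.any(p_c > 1):
        raise ValueError("p_c must lie in (0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    w = (-np.log(p_c) + np.log(alpha)) / np.log(base)
    return float(w) if w.ndim == 0 else w


def make_node_weights(
    scores, alpha: float = DEFAULT_ALPHA, base: float = math.e
) -> dict:
    """Map a score table (DataFrame with gene index and ``p`` column, or a
    mapping gene -> p) to a gene -> weight dict."""
    if hasattr(scores, "columns"):
        p = scores["p"]
        return {g: node_weight(pv, alpha, base) for g, pv in p.items()}
    return {g: node_weight(pv, alpha, base) for g, pv in dict(scores).items()}


# ---------------------------------------------------------------------------
# solution containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubnetworkSolution:
    """A connected tree solution of the (heuristic) PCST.

    ``profit = sum(node weights) - edge_cost * len(tree_edges)`` and the tree
    property ``len(tree_edges) == len(nodes) - 1`` always hold.
    """

    nodes: frozenset
    tree_edges: frozenset
    profit: float
    node_weights: dict
    rank: int = 1

    def __post_init__(self):
        if not self.nodes:
            raise ValueError("a subnetwork solution cannot be empty")
        if len(self.tree_edges) != len(self.nodes) - 1:
            raise ValueError("solution edges do not form a spanning tree")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def sorted_nodes(self) -> list:
        return sorted(self.nodes)

    def to_dict(self) -> dict:
        return {
            "nodes": self.sorted_nodes(),
            "tree_edges": sorted(tuple(sorted(e)) for e in self.tree_edges),
            "profit": self.profit,
            "node_weights": {n: self.node_weights[n] for n in self.sorted_nodes()},
            "rank": self.rank,
        }


@dataclass(frozen=True)
class SubgraphStats:
    """Summary statistics of the subgraph induced in the full network."""

    n_nodes: int
    n_edges_induced: int
    clustering_coefficient: float
    score_sum: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges_induced": self.n_edges_induced,
            "clustering_coefficient": self.clustering_coefficient,
            "score_sum": self.score_sum,
        }


# ---------------------------------------------------------------------------
# heuristic PCST
# ---------------------------------------------------------------------------

def _adjacency(network: nx.Graph) -> dict:
    return {n: sorted(network.adj[n]) for n in network.nodes}


def _strong_prune(adj: Mapping, root, net_value: Mapping, root_value: float):
    """Bottom-up pruning of a rooted tree: drop every subtree whose total
    contribution is negative.  Returns (kept node set, profit)."""
    parent = {root: None}
    order = [root]
    for u in order:
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                order.append(v)
    value = {}
    keep_children: dict = {u: [] for u in order}
    for u in reversed(order):
        val = root_value if u == root else net_value[u]
        for c in keep_children[u]:
            val += value[c]
        value[u] = val
        p = parent[u]
        if p is not None and val > 0:
            keep_children[p].append(u)
    kept = {root}
    stack = list(keep_children[root])
    while stack:
        u = stack.pop()
        kept.add(u)
        stack.extend(keep_children[u])
    return kept, value[root]


def _spanning_tree_edges(adj_full: Mapping, nodes: set) -> dict:
    """BFS spanning adjacency of the subgraph induced by ``nodes``.

    Assumes the induced subgraph is connected."""
    start = min(nodes)
    tree_adj: dict = {n: [] for n in nodes}
    seen = {start}
    queue = [start]
    while queue:
        u = queue.pop()
        for v in adj_full[u]:
            if v in nodes and v not in seen:
                seen.add(v)
                tree_adj[u].append(v)
                tree_adj[v].append(u)
                queue.append(v)
    if len(seen) != len(nodes):
        raise ValueError("node set is not connected in the network")
    return tree_adj


def _singleton(node, weights) -> SubnetworkSolution:
    return SubnetworkSolution(
        nodes=frozenset([node]),
        tree_edges=frozenset(),
        profit=float(weights[node]),
        node_weights={node: float(weights[node])},
    )


def heuristic_pcst(
    network: nx.Graph,
    weights: Mapping,
    edge_cost: float = 0.0,
    rank: int = 1,
) -> SubnetworkSolution:
    """Heuristic maximum-profit connected subgraph (prize-collecting Steiner
    tree) on a node-prized graph.

    Parameters
    ----------
    network : undirected graph of gene interactions.
    weights : gene -> prize; positive = signal, non-positive = null.
    edge_cost : uniform cost per tree edge (default 0; null-node prices
        already act as connection costs).

    Returns the best tree found; if no node has positive weight, the single
    maximum-weight node is returned (and logged).
    """
    if network.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    missing = [n for n in network.nodes if n not in weights]
    if missing:
        raise ValueError(f"weights missing for nodes: {sorted(missing)[:5]}")
    if edge_cost < 0:
        raise ValueError("edge_cost must be non-negative")

    adj = _adjacency(network)
    nodes = sorted(adj)
    signal = {n for n in nodes if weights[n] > 0}
    if not signal:
        best = max(nodes, key=lambda n: (weights[n], n))
        logger.info("no signal nodes at this threshold; returning singleton %s", best)
        return SubnetworkSolution(
            nodes=frozenset([best]),
            tree_edges=frozenset(),
            profit=float(weights[best]),
            node_weights={best: float(weights[best])},
            rank=rank,
        )

    # components of the signal subgraph -> terminals
    comp_of: dict = {}
    comps: list = []
    for s in sorted(signal):
        if s in comp_of:
            continue
        cid = len(comps)
        members = [s]
        comp_of[s] = cid
        queue = [s]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v in signal and v not in comp_of:
                    comp_of[v] = cid
                    members.append(v)
                    queue.append(v)
        comps.append(sorted(members))

    # multi-source Dijkstra over connection costs (Mehlhorn-style Voronoi)
    node_price = {
        n: (0.0 if n in signal else -float(weights[n])) for n in nodes
    }
    dist = {}
    pred = {}
    terminal = {}
    heap = []
    for cid, members in enumerate(comps):
        for m in members:
            dist[m] = 0.0
            pred[m] = None
            terminal[m] = cid
            heap.append((0.0, m))
    heapq.heapify(heap)
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in adj[u]:
            nd = d + edge_cost + node_price[v]
            if v not in dist or nd < dist[v] - 1e-15:
                dist[v] = nd
                pred[v] = u
                terminal[v] = terminal[u]
                heapq.heappush(heap, (nd, v))

    # cheapest inter-terminal connections via Voronoi boundary edges
    best_link: dict = {}
    for u, v in network.edges:
        if u not in terminal or v not in terminal:
            continue
        cu, cv = terminal[u], terminal[v]
        if cu == cv:
            continue
        key = (min(cu, cv), max(cu, cv))
        d = dist[u] + dist[v] + edge_cost
        if key not in best_link or d < best_link[key][0]:
            best_link[key] = (d, u, v)

    # minimum spanning forest over the supernode metric (Kruskal)
    parent = list(range(len(comps)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    forest_links = []
    for key in sorted(best_link, key=lambda k: (best_link[k][0], k)):
        a, b = key
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            forest_links.append(best_link[key])

    # expand: signal members + shortest-path nodes of chosen links
    selected = set()
    for members in comps:
        selected.update(members)
    for _, u, v in forest_links:
        for x in (u, v):
            while x is not None:
                selected.add(x)
                x = pred[x]

    # evaluate each connected piece: spanning tree + strong pruning
    net_value = {n: float(weights[n]) - edge_cost for n in selected}
    pieces = []
    unvisited = set(selected)
    while unvisited:
        start = min(unvisited)
        piece = {start}
        queue = [start]
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v in unvisited and v not in piece:
                    piece.add(v)
                    queue.append(v)
        unvisited -= piece
        pieces.append(piece)

    best_solution = None
    for piece in pieces:
        tree_adj = _spanning_tree_edges(adj, piece)
        roots = sorted(n for n in piece if n in signal)
        if len(roots) > 200:
            roots = sorted(roots, key=lambda n: -weights[n])[:200]
        for root in roots:
            kept, profit = _strong_prune(
                tree_adj, root, net_value, float(weights[root])
            )
            if best_solution is None or profit > best_solution[1] + 1e-12:
                best_solution = (kept, profit)

    kept, profit = best_solution
    tree_adj = _spanning_tree_edges(adj, kept)
    edges = frozenset(
        frozenset((u, v)) for u in tree_adj for v in tree_adj[u] if u < v
    )
    # recompute profit exactly from the definition
    profit = sum(float(weights[n]) for n in kept) - edge_cost * len(edges)
    return SubnetworkSolution(
        nodes=frozenset(kept),
        tree_edges=edges,
        profit=float(profit),
        node_weights={n: float(weights[n]) for n in kept},
        rank=rank,
    )


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------

def brute_force_pcst(
    network: nx.Graph, weights: Mapping, edge_cost: float = 0.0
) -> SubnetworkSolution:
    """Exact maximum-profit connected subgraph by exhaustive enumeration.

    Only feasible for small graphs (<= 15 nodes).  Profit of a k-node
    connected subset uses k-1 tree edges (uniform edge cost).  Ties broken
    toward fewer nodes, then the lexicographically smallest sorted node set.
    """
    nodes = sorted(network.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("network has no nodes")
    if n > 15:
        raise ValueError(
            "brute force limited to 15 nodes; use heuristic_pcst instead"
        )
    index = {v: i for i, v in enumerate(nodes)}
    nbr_mask = [0] * n
    for u, v in network.edges:
        iu, iv = index[u], index[v]
        nbr_mask[iu] |= 1 << iv
        nbr_mask[iv] |= 1 << iu
    w = [float(weights[v]) for v in nodes]

    best = None  # (profit, k, node tuple, mask)
    for mask in range(1, 1 << n):
        # connectivity by bit BFS from lowest set bit
        seed = mask & (-mask)
        reach = seed
        frontier = seed
        while frontier:
            nxt = 0
            m = frontier
            while m:
                b = m & (-m)
                m ^= b
                nxt |= nbr_mask[b.bit_length() - 1]
            nxt &= mask & ~reach
            reach |= nxt
            frontier = nxt
        if reach != mask:
            continue
        members = [nodes[i] for i in range(n) if mask >> i & 1]
        k = len(members)
        profit = sum(w[index[v]] for v in members) - edge_cost * (k - 1)
        key = (-profit, k, tuple(members))
        if best is None or key < best[0]:
            best = (key, members, profit)

    _, members, profit = best
    member_set = set(members)
    tree_adj = _spanning_tree_edges(_adjacency(network), member_set)
    edges = frozenset(
        frozenset((u, v)) for u in tree_adj for v in tree_adj[u] if u < v
    )
    return SubnetworkSolution(
        nodes=frozenset(members),
        tree_edges=edges,
        profit=float(profit),
        node_weights={v: float(weights[v]) for v in members},
    )


# ---------------------------------------------------------------------------
# iteration & statistics
# ---------------------------------------------------------------------------

def iterate_subnetworks(
    network: nx.Graph,
    weights: Mapping,
    k: int = 1,
    edge_cost: float = 0.0,
    null_weight: float | None = None,
) -> list[SubnetworkSolution]:
    """Discover up to ``k`` subnetworks, resetting each round's members to a
    null weight before the next round.

    ``null_weight`` defaults to the minimum observed weight (the prize a gene
    with p = 1 would carry, i.e. ``log(alpha)``, whenever such genes exist).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    weights = {n: float(weights[n]) for n in network.nodes}
    if null_weight is None:
        null_weight = min(weights.values())
    solutions = []
    for r in range(1, k + 1):
        sol = heuristic_pcst(network, weights, edge_cost=edge_cost, rank=r)
        solutions.append(sol)
        for n in sol.nodes:
            weights[n] = float(null_weight)
    return solutions


def subgraph_stats(
    network: nx.Graph, node_set: Iterable, scores: Mapping
) -> SubgraphStats:
    """Statistics of the subgraph induced in the FULL network by ``node_set``.

    ``scores`` maps gene -> constraint score (the signed Z); ``score_sum`` is
    the total constraint explained by the members.  The clustering
    coefficient is the mean local clustering over induced nodes, with
    degree < 2 nodes contributing 0.
    """
    node_set = set(node_set)
    if not node_set:
        raise ValueError("empty node set")
    extra = node_set - set(network.nodes)
    if extra:
        raise ValueError(f"nodes not in network: {sorted(extra)[:5]}")
    sub = network.subgraph(node_set)
    cc = nx.average_clustering(sub, count_zeros=True) if len(node_set) > 0 else 0.0
    return SubgraphStats(
        n_nodes=len(node_set),
        n_edges_induced=sub.number_of_edges(),
        clustering_coefficient=float(cc),
        score_sum=float(sum(float(scores[n]) for n in node_set)),
    )


def binomial_excess_test(n_hits: int, n_genes: int, p0: float) -> float:
    """Exact upper-tail binomial probability ``P(X >= n_hits)`` for observing
    at least ``n_hits`` genes passing a per-gene threshold ``p0`` among
    ``n_genes`` genes.

    Computed in log space and summed with logsumexp so extreme tails (far
    below double-precision normal range) are still returned as (sub)normal
    floats rather than flushed to zero.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= n_hits <= n_genes:
        raise ValueError("n_hits must lie in [0, n_genes]")
    if n_hits == 0:
        return 1.0
    from scipy.special import logsumexp

    k = np.arange(n_hits, n_genes + 1)
    logp = logsumexp(stats.binom.logpmf(k, n_genes, p0))
    return float(np.exp(logp))


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class PCSTModuleFinder(BaseEstimator):
    """Estimator facade over the heuristic PCST module search.

    Parameters
    ----------
    alpha : significance threshold on the constraint p-value; genes below it
        are signal nodes (default 5e-6, a Bonferroni-style genome-wide cut).
    edge_cost : uniform cost per tree edge (default 0).
    n_modules : how many subnetworks to discover iteratively.
    log_base : base of the log in the weight transform (rescaling only).

    Attributes (after :meth:`fit`)
    ------------------------------
    solutions_ : list of :class:`SubnetworkSolution`, in discovery order.
    nodes_ : frozenset, members of the rank-1 solution.
    profit_ : float, profit of the rank-1 solution.
    weights_ : dict, gene -> node weight used in the search.
    stats_ : :class:`SubgraphStats` of the rank-1 solution in the full graph.
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        edge_cost: float = 0.0,
        n_modules: int = 1,
        log_base: float = math.e,
    ):
        self.alpha = alpha
        self.edge_cost = edge_cost
        self.n_modules = n_modules
        self.log_base = log_base

    def fit(self, network: nx.Graph, scores):
        """Find subnetworks.  ``scores`` is a DataFrame indexed by gene with
        columns ``z`` and ``p`` (see :func:`prizenet.io.read_gene_scores`)."""
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        missing = set(network.nodes) - set(scores.index)
        if missing:
            raise ValueError(f"scores missing for genes: {sorted(missing)[:5]}")
        scores = scores.loc[list(network.nodes)]
        self.weights_ = make_node_weights(scores, self.alpha, self.log_base)
        self.solutions_ = iterate_subnetworks(
            network,
            self.weights_,
            k=self.n_modules,
            edge_cost=self.edge_cost,
            null_weight=node_weight(1.0, self.alpha, self.log_base),
        )
        top = self.solutions_[0]
        self.nodes_ = top.nodes
        self.profit_ = top.profit
        self.stats_ = subgraph_stats(network, top.nodes, scores["z"])
        return self
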
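"""Permutation null models for subnetwork statistics.

The module search always returns *some* solution, so significance is
assessed empirically: constraint scores are randomly reassigned to genes
(optionally within degree bins), the search is re-run on each permuted score
set, and the observed subnetwork's statistics are compared with the null
records.  The per-permutation top subnetworks ("resampled subnetworks") are
retained for the tissue-specificity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .network import (
    DEFAULT_ALPHA,
    SubgraphStats,
    SubnetworkSolution,
    heuristic_pcst,
    make_node_weights,
    subgraph_stats,
)

logger = logging.getLogger(__name__)

STAT_NAMES = ("n_nodes", "n_edges_induced", "clustering_coefficient", "score_sum")

__all__ = [
    "STAT_NAMES",
    "NullDistribution",
    "permute_node_scores",
    "degree_bins",
    "null_distribution",
    "empirical_p",
    "format_empirical_p",
    "ScorePermutationNull",
]


@dataclass
class NullDistribution:
    """Per-iteration top-subnetwork statistics under permuted scores."""

    records: pd.DataFrame  # one row per iteration, columns = STAT_NAMES
    solutions: list  # SubnetworkSolution per iteration (rank 1 only)
    n_iterations: int
    seed: int
    mode: str

    def values(self, stat: str) -> np.ndarray:
        return self.records[stat].to_numpy()


def degree_bins(network: nx.Graph, min_bin_size: int = 10) -> dict:
    """Assign every node to a log2-spaced degree bin, merging sparse bins
    upward until each holds at least ``min_bin_size`` genes."""
    raw = {n: int(np.floor(np.log2(max(d, 1)))) for n, d in network.degree()}
    levels = sorted(set(raw.values()))
    counts = {lv: sum(1 for b in raw.values() if b == lv) for lv in levels}
    merged: dict = {}
    current: list = []
    size = 0
    last_label = None
    for lv in levels:
        current.append(lv)
        size += counts[lv]
        if size >= min_bin_size:
            last_label = current[0]
            for c in current:
                merged[c] = last_label
            current, size = [], 0
    if current:  # trailing sparse bins merge into the previous full bin
        target = last_label if last_label is not None else current[0]
        for c in current:
            merged[c] = target
    return {n: merged[b] for n, b in raw.items()}


def permute_node_scores(
    scores: pd.DataFrame,
    network: nx.Graph,
    mode: str = "uniform",
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Randomly reassign the (z, p) score rows to genes.

    ``uniform`` draws a uniformly random bijection over all network genes;
    ``degree_matched`` permutes only within log2-spaced degree bins so the
    permuted signal set keeps the observed degree profile.  Either way the
    score multiset is conserved exactly.
    """
    rng = np.random.default_rng(rng)
    genes = sorted(network.nodes)
    missing = [g for g in genes if g not in scores.index]
    if missing:
        raise ValueError(f"scores missing for genes: {missing[:5]}")
    sub = scores.loc[genes]
    if mode == "uniform":
        perm = rng.permutation(len(genes))
    elif mode == "degree_matched":
        bins = degree_bins(network)
        perm = np.arange(len(genes))
        by_bin: dict = {}
        for i, g in enumerate(genes):
            by_bin.setdefault(bins[g], []).append(i)
        for _, idx in sorted(by_bin.items()):
            idx = np.array(idx)
            perm[idx] = idx[rng.permutation(len(idx))]
    else:
        raise ValueError(f"unknown permutation mode: {mode!r}")
    out = sub.iloc[perm].copy()
    out.index = pd.Index(genes, name=sub.index.name)
    return out


def null_distribution(
    network: nx.Graph,
    scores: pd.DataFrame,
    n_iter: int = 1000,
    mode: str = "uniform",
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    edge_cost: float = 0.0,
    keep_solutions: bool = True,
) -> NullDistribution:
    """Run the module search on ``n_iter`` permuted score sets, recording the
    rank-1 subnetwork's statistics each time."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    solutions = []
    for it in range(n_iter):
        perm = permute_node_scores(scores, network, mode=mode, rng=rng)
        weights = make_node_weights(perm, alpha)
        try:
            sol = heuristic_pcst(network, weights, edge_cost=edge_cost)
            st = subgraph_stats(network, sol.nodes, perm["z"])
        except Exception as exc:  # pragma: no cover - solver errors are rare
            raise RuntimeError(f"permutation iteration {it} failed") from exc
        rows.append(st.to_dict())
        if keep_solutions:
            solutions.append(sol)
    return NullDistribution(
        records=pd.DataFrame(rows),
        solutions=solutions,
        n_iterations=n_iter,
        seed=-1 if seed is None else int(seed),
        mode=mode,
    )


def empirical_p(observed: float, null_values, side: str = "ge") -> float:
    """Permutation p-value ``(r + 1) / (n + 1)`` with ties counted as
    exceedances (conservative)."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null distribution is empty")
    if side == "ge":
        r = int(np.sum(null_values >= observed))
    elif side == "le":
        r = int(np.sum(null_values <= observed))
    else:
        raise ValueError("side must be 'ge' or 'le'")
    return (r + 1) / (null_values.size + 1)


def format_empirical_p(r: int, n: int) -> str:
    """Render a permutation p-value in reporting style: ``p < 1/n`` when no
    null value reached the observation (e.g. 'p < 0.001' at 1000
    permutations, 'p < 0.00125' at 800), else ``p = (r+1)/(n+1)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if r == 0:
        return f"p < {1 / n:g}"
    return f"p = {(r + 1) / (n + 1):.5g}"


class ScorePermutationNull(BaseEstimator):
    """Estimator facade: observed module statistics vs a score-permutation null.

    Attributes (after :meth:`fit`)
    ------------------------------
    observed_ : :class:`SubgraphStats` of the observed rank-1 subnetwork.
    solution_ : the observed :class:`SubnetworkSolution`.
    null_ : :class:`NullDistribution`.
    pvalues_ : dict statistic -> empirical p (side 'ge').
    rendered_ : dict statistic -> reporting-style string.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        mode: str = "uniform",
        alpha: float = DEFAULT_ALPHA,
        edge_cost: float = 0.0,
        random_state: int | None = None,
    ):
        self.n_permutations = n_permutations
        self.mode = mode
        self.alpha = alpha
        self.edge_cost = edge_cost
        self.random_state = random_state

    def fit(self, network: nx.Graph, scores: pd.DataFrame):
        weights = make_node_weights(scores.loc[list(network.nodes)], self.alpha)
        self.solution_ = heuristic_pcst(network, weights, edge_cost=self.edge_cost)
        self.observed_ = subgraph_stats(network, self.solution_.nodes, scores["z"])
        self.null_ = null_distribution(
            network,
            scores,
            n_iter=self.n_permutations,
            mode=self.mode,
            seed=self.random_state,
            alpha=self.alpha,
            edge_cost=self.edge_cost,
        )
        obs = self.observed_.to_dict()
        self.pvalues_ = {}
        self.rendered_ = {}
        for stat in STAT_NAMES:
            nv = self.null_.values(stat)
            self.pvalues_[stat] = empirical_p(obs[stat], nv, side="ge")
            r = int(np.sum(nv >= obs[stat]))
            self.rendered_[stat] = format_empirical_p(r, self.n_permutations)
        return self
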
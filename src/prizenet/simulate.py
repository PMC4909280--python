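"""Synthetic fixtures with planted structure for every pipeline stage.

The generators emulate the statistical world the analyses assume: a sparse
undirected interaction network carrying a connected module of high-constraint
genes among mostly-null scores, and a replicate-structured multi-tissue
expression atlas in which that module is coordinately up-regulated in a small
set of active tissues.  Defaults (500 genes, Erdos-Renyi p = 0.01, 25-gene
module, signal mean Z = 6, 10 tissues x 3 replicates, effect +3 on a
log-intensity-like scale, noise sd 0.5) are chosen so that the module is
detectable but not trivial: a mean Z of 6 sits inside the observed range of
strongly constrained genes (~2 to 10), and a 6-fold-log2-ish shift of 3 with
sd 0.5 mirrors tissue-restricted array intensities.  All generators are
deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .network import constraint_p_from_z
from .prefexp import ExpressionAtlas

__all__ = [
    "FixtureSpec",
    "gen_network_with_module",
    "gen_constraint_scores",
    "gen_expression_atlas",
    "gen_annotations",
    "generate_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one planted-module world."""

    seed: int = 0
    n_genes: int = 500
    network_model: str = "er"  # 'er' | 'degree_skewed'
    er_p: float = 0.01
    attachment_m: int = 3  # edges per new node in the degree-skewed model
    module_size: int = 25
    module_extra_edge_p: float = 0.2  # extra intra-module edges beyond the tree
    mu_signal: float = 6.0
    n_tissues: int = 10
    replicates: int = 3
    active_tissues: tuple = ("tissue03",)
    effect: float = 3.0
    noise_sd: float = 0.5

    def __post_init__(self):
        if self.module_size > self.n_genes:
            raise ValueError("planted module larger than the gene universe")
        if self.module_size < 1 or self.n_genes < 2:
            raise ValueError("sizes must be positive")

    def tissue_names(self) -> list:
        return [f"tissue{i:02d}" for i in range(self.n_tissues)]


def _gene_names(n: int) -> list:
    return [f"g{i:04d}" for i in range(n)]


def gen_network_with_module(spec: FixtureSpec):
    """Background graph plus an embedded connected module.

    Returns (network, planted node set).  The module is a random spanning
    tree over randomly chosen nodes plus extra intra-module edges, so it is
    connected by construction regardless of the background model.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    G = nx.Graph()
    G.add_nodes_from(genes)
    n = spec.n_genes
    if spec.network_model == "er":
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.size) < spec.er_p
        for a, b in zip(iu[mask], ju[mask]):
            G.add_edge(genes[a], genes[b])
    elif spec.network_model == "degree_skewed":
        m = spec.attachment_m
        targets = list(range(m))
        repeated: list = list(range(m))
        for v in range(m, n):
            for t in set(targets):
                G.add_edge(genes[v], genes[t])
                repeated.extend([v, t])
            targets = [repeated[k] for k in rng.integers(0, len(repeated), m)]
    else:
        raise ValueError(f"unknown network model: {spec.network_model!r}")

    planted_idx = rng.choice(n, size=spec.module_size, replace=False)
    planted = [genes[i] for i in sorted(planted_idx)]
    # random spanning tree over the planted nodes
    order = list(rng.permutation(spec.module_size))
    for k in range(1, spec.module_size):
        prev = order[int(rng.integers(0, k))]
        G.add_edge(planted[order[k]], planted[prev])
    # optional extra intra-module edges
    for a in range(spec.module_size):
        for b in range(a + 1, spec.module_size):
            if rng.random() < spec.module_extra_edge_p:
                G.add_edge(planted[a], planted[b])
    return G, frozenset(planted)


def gen_constraint_scores(
    network: nx.Graph, planted, mu_signal: float = 6.0, seed: int = 0
) -> pd.DataFrame:
    """Constraint Z scores: null genes ~ N(0,1), planted genes ~ N(mu, 1);
    p is the upper-tail normal probability."""
    planted = set(planted)
    extra = planted - set(network.nodes)
    if extra:
        raise ValueError(f"planted genes not in network: {sorted(extra)[:5]}")
    rng = np.random.default_rng(seed)
    genes = sorted(network.nodes)
    z = rng.normal(0.0, 1.0, len(genes))
    for k, g in enumerate(genes):
        if g in planted:
            z[k] = rng.normal(mu_signal, 1.0)
    return pd.DataFrame(
        {"z": z, "p": constraint_p_from_z(z)},
        index=pd.Index(genes, name="gene_id"),
    )


def gen_expression_atlas(spec: FixtureSpec, planted, genes=None) -> ExpressionAtlas:
    """Replicate-structured atlas: baseline per gene ~ N(8, 1) shared across
    samples, +effect for planted genes in active tissues, replicate noise
    N(0, noise_sd)."""
    planted = set(planted)
    unknown = set(spec.active_tissues) - set(spec.tissue_names())
    if unknown:
        raise ValueError(f"active tissues not in atlas: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed + 1)
    if genes is None:
        genes = _gene_names(spec.n_genes)
    genes = sorted(genes)
    tissues = spec.tissue_names()
    samples = [f"{t}_r{r}" for t in tissues for r in range(1, spec.replicates + 1)]
    sample_tissue = [t for t in tissues for _ in range(spec.replicates)]
    base = rng.normal(8.0, 1.0, len(genes))
    X = base[:, None] + rng.normal(0.0, spec.noise_sd, (len(genes), len(samples)))
    active = {t for t in spec.active_tissues}
    planted_rows = np.array([g in planted for g in genes])
    active_cols = np.array([t in active for t in sample_tissue])
    X[np.ix_(planted_rows, active_cols)] += spec.effect
    matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=samples)
    sample_map = pd.Series(sample_tissue, index=pd.Index(samples, name="sample"))
    return ExpressionAtlas(matrix=matrix, sample_map=sample_map)


def gen_annotations(
    genes,
    n_sets: int = 20,
    enriched_set=(),
    overlap_rate: float = 1.0,
    set_size_range: tuple = (10, 50),
    n_categories: int = 5,
    seed: int = 0,
):
    """Random gene sets plus one set overlapping ``enriched_set`` at
    ``overlap_rate``, and a gene -> disease-category annotation table with one
    category enriched in ``enriched_set``.

    Returns (gene set dict, annotation dict gene -> set of categories).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(genes)
    enriched = sorted(set(enriched_set))
    if set(enriched) - set(genes):
        raise ValueError("enriched set must be drawn from the gene universe")
    lo, hi = set_size_range
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"set{k:03d}"] = {genes[i] for i in members}
    if enriched:
        take = [g for g in enriched if rng.random() < overlap_rate]
        pad_n = max(0, lo - len(take))
        others = [g for g in genes if g not in set(take)]
        pad = [others[i] for i in rng.choice(len(others), size=pad_n, replace=False)]
        sets["set_enriched"] = set(take) | set(pad)
    cats = [f"cat{c}" for c in range(n_categories)]
    annotation = {}
    for g in genes:
        mine = {c for c in cats if rng.random() < 0.1}
        if g in set(enriched) and rng.random() < 0.8:
            mine.add("cat0")
        if mine:
            annotation[g] = mine
    return sets, annotation


def generate_fixture(spec: FixtureSpec | None = None, seed: int | None = None):
    """End-to-end fixture: network, planted truth, scores and atlas.

    Returns a dict with keys ``network``, ``planted``, ``scores``, ``atlas``,
    ``spec``."""
    if spec is None:
        spec = FixtureSpec()
    if seed is not None:
        spec = replace(spec, seed=int(seed))
    network, planted = gen_network_with_module(spec)
    scores = gen_constraint_scores(network, planted, spec.mu_signal, spec.seed)
    atlas = gen_expression_atlas(spec, planted)
    return {
        "network": network,
        "planted": planted,
        "scores": scores,
        "atlas": atlas,
        "spec": spec,
    }
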
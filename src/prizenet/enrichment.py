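"""Gene-set and disease-annotation enrichment for a subnetwork.

Hypergeometric over-representation and rank-based Kolmogorov-Smirnov tests
against GMT gene-set collections, and Fisher's exact tests against
gene -> disease-category annotation tables.  Gene sets are intersected with
the analysis background (the genes present in both the interaction network
and the expression atlas) before testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hypergeometric_enrichment",
    "ks_enrichment",
    "fisher_annotation_enrichment",
]


def _check_subset(query, background):
    query = set(query)
    background = set(background)
    extra = query - background
    if extra:
        raise ValueError(f"query genes not in background: {sorted(extra)[:5]}")
    return query, background


def hypergeometric_enrichment(
    query, background, gene_sets: dict, ranking=None
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    Each set is first intersected with ``background`` ("mapped" size); the p
    is the probability of >= the observed overlap when drawing |query| genes
    from |background| with |mapped| marked.  If ``ranking`` (genes ordered by
    decreasing score) is given, a two-sample KS column on member vs
    non-member ranks is added.  A Benjamini-Hochberg column accompanies the
    raw hypergeometric p-values.
    """
    query, background = _check_subset(query, background)
    M, N = len(background), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name])
        mapped = members & background
        overlap = mapped & query
        n = len(mapped)
        k = len(overlap)
        if n == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, M, n, N))
        row = {
            "set": name,
            "all": len(members),
            "mapped": n,
            "overlap": k,
            "hypergeom_p": min(p, 1.0),
        }
        if ranking is not None and len(mapped) > 0:
            try:
                row["ks_p"] = ks_enrichment(ranking, mapped)
            except ValueError:
                row["ks_p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows).set_index("set")
    out["hypergeom_bh"] = stats.false_discovery_control(out["hypergeom_p"])
    return out


def ks_enrichment(ranking, gene_set) -> float:
    """Two-sample KS p comparing the rank positions of set members against
    non-members in a score-ordered gene ranking."""
    ranking = list(ranking)
    members = set(gene_set) & set(ranking)
    if not members:
        raise ValueError("gene set does not intersect the ranking")
    in_ranks = [i + 1 for i, g in enumerate(ranking) if g in members]
    out_ranks = [i + 1 for i, g in enumerate(ranking) if g not in members]
    if not out_ranks:
        raise ValueError("gene set covers the whole ranking; no complement")
    return float(stats.ks_2samp(in_ranks, out_ranks).pvalue)


def fisher_annotation_enrichment(
    query, background, annotation: dict, category: str = "all"
) -> pd.DataFrame:
    """Two-sided Fisher's exact test of category membership in query vs rest.

    ``annotation`` maps gene -> set of category labels; the 2x2 table is
    (in query x carries category) over the background.  ``category='all'``
    tests every category in the vocabulary, plus an 'any' row for carrying
    at least one annotation.
    """
    query, background = _check_subset(query, background)
    vocab = sorted({c for g in background for c in annotation.get(g, ())})
    if category == "all":
        categories = ["any"] + vocab
    else:
        if category not in vocab and category != "any":
            raise ValueError(f"category {category!r} not in annotation vocabulary")
        categories = [category]
    rest = background - query
    rows = []
    for cat in categories:
        def has(g):
            anns = annotation.get(g, ())
            return bool(anns) if cat == "any" else cat in anns

        a = sum(1 for g in query if has(g))
        b = len(query) - a
        c = sum(1 for g in rest if has(g))
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "category": cat,
                "query_with": a,
                "query_without": b,
                "background_with": c,
                "background_without": d,
                "odds_ratio": float(odds),
                "fisher_p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("category")
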
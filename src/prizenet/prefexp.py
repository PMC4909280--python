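"""Preferential tissue expression from a replicate-structured atlas.

A gene x sample expression matrix with a sample -> tissue map is reduced to
per-gene, per-tissue preferential-expression scores in [-1, 1] and binary
calls:

1. quantile-normalize samples (and optionally collapse transcripts to genes
   by the maximum-mean transcript);
2. fit a one-way layout per gene across all samples (tissue means, pooled
   residual variance with df = n_samples - n_tissues);
3. shrink gene-wise variances with an empirical-Bayes scaled-inverse-chi^2
   prior (method of moments on log s^2 via digamma/trigamma), yielding
   moderated t-statistics for every ordered tissue pair;
4. per (gene, tissue), sum the pairwise mean differences whose p-value
   passes a Bonferroni-corrected per-comparison threshold, and rescale all
   sums by the global maximum absolute sum;
5. call a gene preferentially expressed in a tissue when its rescaled score
   strictly exceeds a threshold (default 0.1).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionAtlas",
    "EBayesParams",
    "PairwiseDEResult",
    "quantile_normalize",
    "collapse_to_genes",
    "fit_ebayes",
    "pairwise_moderated_de",
    "preferential_scores",
    "call_preferential",
    "threshold_sweep",
    "PreferentialExpressionScorer",
]

_DF_CAP = 1e6  # stands in for an infinite prior df


@dataclass
class ExpressionAtlas:
    """Expression matrix (genes/transcripts x samples) plus sample -> tissue map."""

    matrix: pd.DataFrame
    sample_map: pd.Series

    def __post_init__(self):
        missing = [s for s in self.matrix.columns if s not in self.sample_map.index]
        if missing:
            raise ValueError(f"samples missing from sample map: {missing[:5]}")
        self.sample_map = self.sample_map.loc[list(self.matrix.columns)]
        if self.sample_map.nunique() < 2:
            raise ValueError("atlas must cover at least 2 distinct tissues")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def tissues(self) -> list:
        return sorted(self.sample_map.unique())


@dataclass(frozen=True)
class EBayesParams:
    """Scaled-inverse-chi^2 prior on gene-wise residual variances."""

    d0: float  # prior degrees of freedom (capped at 1e6 for "infinite")
    s0_sq: float  # prior variance

    def posterior_variance(self, s_sq, d: float):
        """Shrunk variance ``(d0*s0^2 + d*s^2) / (d0 + d)`` — always between
        the gene-wise estimate and the prior."""
        s_sq = np.asarray(s_sq, dtype=float)
        return (self.d0 * self.s0_sq + d * s_sq) / (self.d0 + d)


@dataclass
class PairwiseDEResult:
    """All-pairs moderated differential expression for one atlas.

    ``beta[g, t, u] = mean(t) - mean(u)`` (antisymmetric), ``pvalue`` is the
    symmetric two-sided p from a t distribution with ``d0 + d`` df.
    """

    genes: list
    tissues: list
    beta: np.ndarray  # (G, T, T)
    tstat: np.ndarray  # (G, T, T)
    pvalue: np.ndarray  # (G, T, T); diagonal = 1
    df_residual: float
    s_sq: np.ndarray  # (G,) gene-wise residual variances
    ebayes: EBayesParams


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of per-rank means.

    Within-column ranks are preserved; ties receive the average of the
    reference values at the positions they occupy.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values")
    if matrix.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is a no-op")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average assigned values over tied input values
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_to_genes(matrix: pd.DataFrame, transcript_to_gene: pd.Series) -> pd.DataFrame:
    """Per gene keep the single transcript with maximal mean expression over
    all samples (ties -> lexicographically smaller transcript id); unmapped
    transcripts are dropped with a logged count."""
    mapped = matrix.index.intersection(transcript_to_gene.index)
    n_dropped = len(matrix.index) - len(mapped)
    if n_dropped:
        logger.info("dropping %d unmapped transcripts", n_dropped)
    sub = matrix.loc[mapped]
    means = sub.mean(axis=1)
    info = pd.DataFrame(
        {
            "gene": transcript_to_gene.loc[mapped].to_numpy(),
            "mean": means.to_numpy(),
        },
        index=mapped,
    )
    info = info.sort_index().sort_values("mean", ascending=False, kind="stable")
    keep = info.groupby("gene", sort=True).head(1)
    out = sub.loc[keep.index]
    out.index = pd.Index(keep["gene"].to_numpy(), name="gene_id")
    return out.sort_index()


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def fit_ebayes(s_sq, d: float) -> EBayesParams:
    """Method-of-moments fit of the variance prior from gene-wise residual
    variances ``s_sq`` with shared residual df ``d``.

    With ``e_g = log s^2_g - digamma(d/2) + log(d/2)``, the prior df solves
    ``trigamma(d0/2) = var(e) - trigamma(d/2)`` and
    ``s0^2 = exp(mean(e) + digamma(d0/2) - log(d0/2))``.  When the moment
    equation has no positive solution the prior is effectively a point mass
    (d0 capped at 1e6, s0^2 = exp(mean(e))).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    if s_sq.size < 2:
        raise ValueError("need at least 2 genes to fit the variance prior")
    if d < 1:
        raise ValueError("residual df must be >= 1")
    z = np.log(np.clip(s_sq, 1e-300, None))
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, _DF_CAP)
        s0 = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = _DF_CAP
        s0 = math.exp(emean)
    return EBayesParams(d0=float(d0), s0_sq=float(s0))


# ---------------------------------------------------------------------------
# pairwise moderated differential expression
# ---------------------------------------------------------------------------

def pairwise_moderated_de(
    atlas: ExpressionAtlas, d0_override: float | None = None
) -> PairwiseDEResult:
    """Moderated t-statistics for every ordered tissue pair under a shared
    one-way layout per gene.

    ``d0_override = 0`` disables shrinkage and reproduces the ordinary
    pooled-variance t-statistic.
    """
    tissues = atlas.tissues
    T = len(tissues)
    if T < 2:
        raise ValueError("need at least 2 tissues")
    X = atlas.matrix.to_numpy(dtype=float)
    G, N = X.shape
    d = N - T
    if d < 1:
        raise ValueError("residual df = n_samples - n_tissues must be >= 1")
    cols = np.array([tissues.index(t) for t in atlas.sample_map.to_numpy()])
    n_t = np.bincount(cols, minlength=T).astype(float)
    if np.any(n_t == 0):
        empty = [tissues[i] for i in np.where(n_t == 0)[0]]
        raise ValueError(f"tissues with zero samples: {empty}")
    # tissue means and pooled residual variance per gene
    sums = np.zeros((G, T))
    np.add.at(sums.T, cols, X.T)
    means = sums / n_t
    resid = X - means[:, cols]
    s_sq = (resid**2).sum(axis=1) / d

    if d0_override is not None:
        if d0_override < 0:
            raise ValueError("d0_override must be >= 0")
        if d0_override == 0:
            eb = EBayesParams(d0=0.0, s0_sq=1.0)  # s0 unused at weight 0
            s_tilde = s_sq.copy()
        else:
            fitted = fit_ebayes(s_sq, d)
            eb = EBayesParams(d0=float(d0_override), s0_sq=fitted.s0_sq)
            s_tilde = eb.posterior_variance(s_sq, d)
    else:
        eb = fit_ebayes(s_sq, d)
        s_tilde = eb.posterior_variance(s_sq, d)

    beta = means[:, :, None] - means[:, None, :]
    pair_scale = np.sqrt(1.0 / n_t[:, None] + 1.0 / n_t[None, :])
    denom = np.sqrt(np.clip(s_tilde, 1e-300, None))[:, None, None] * pair_scale[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / denom
    np.einsum("gtt->gt", tstat)[:] = 0.0
    df_total = min(eb.d0 + d, _DF_CAP)
    pvalue = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    np.einsum("gtt->gt", pvalue)[:] = 1.0
    return PairwiseDEResult(
        genes=list(atlas.matrix.index),
        tissues=tissues,
        beta=beta,
        tstat=tstat,
        pvalue=pvalue,
        df_residual=float(d),
        s_sq=s_sq,
        ebayes=eb,
    )


def preferential_scores(
    de: PairwiseDEResult, family_alpha: float = 0.05
) -> pd.DataFrame:
    """Per (gene, tissue) sum of significant pairwise coefficients, rescaled
    to [-1, 1] by the global maximum absolute sum.

    The per-comparison threshold is ``family_alpha / (T - 1)`` (Bonferroni
    over the T-1 comparisons each tissue enters); with 27 tissues and
    family_alpha 0.05 that is 0.05/26 ~= 0.0019.
    """
    T = len(de.tissues)
    if T < 2:
        raise ValueError("need at least 2 tissues")
    threshold = family_alpha / (T - 1)
    sig = de.pvalue < threshold
    S = np.where(sig, de.beta, 0.0).sum(axis=2)
    max_abs = np.abs(S).max()
    scores = S / max_abs if max_abs > 0 else S
    return pd.DataFrame(scores, index=de.genes, columns=de.tissues)


def call_preferential(scores: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Binary calls: score strictly greater than ``threshold``."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    return (scores > threshold).astype(int)


def threshold_sweep(scores: pd.DataFrame, thresholds) -> dict:
    """One call matrix per threshold, for robustness re-scoring downstream."""
    return {float(t): call_preferential(scores, float(t)) for t in thresholds}


class PreferentialExpressionScorer(BaseEstimator, TransformerMixin):
    """Estimator facade: atlas -> preferential-expression scores and calls.

    Attributes (after :meth:`fit`)
    ------------------------------
    de_ : :class:`PairwiseDEResult`
    ebayes_ : :class:`EBayesParams`
    scores_ : DataFrame gene x tissue in [-1, 1]
    calls_ : DataFrame gene x tissue in {0, 1}
    """

    def __init__(
        self,
        family_alpha: float = 0.05,
        call_threshold: float = 0.1,
        quantile_norm: bool = True,
    ):
        self.family_alpha = family_alpha
        self.call_threshold = call_threshold
        self.quantile_norm = quantile_norm

    def fit(self, atlas: ExpressionAtlas, y=None):
        matrix = atlas.matrix
        if self.quantile_norm:
            matrix = quantile_normalize(matrix)
            atlas = ExpressionAtlas(matrix=matrix, sample_map=atlas.sample_map)
        self.de_ = pairwise_moderated_de(atlas)
        self.ebayes_ = self.de_.ebayes
        self.scores_ = preferential_scores(self.de_, self.family_alpha)
        self.calls_ = call_preferential(self.scores_, self.call_threshold)
        return self

    def transform(self, X=None):
        """Return the fitted score matrix (the atlas is scored during fit)."""
        return self.scores_
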
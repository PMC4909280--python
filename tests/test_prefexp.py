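"""Quantile normalization, variance shrinkage and preferential expression.

The frozen eBayes / moderated-t expectations in ``LIMMA_*`` were produced
once with the Bioconductor limma package (lmFit + contrasts.fit + eBayes) on
the deterministic dataset rebuilt by ``_oracle_atlas`` — an independent
implementation of the same shrinkage model.
"""

import numpy as np
import pandas as pd
import pytest

from prizenet import (
    ExpressionAtlas,
    PreferentialExpressionScorer,
    call_preferential,
    collapse_to_genes,
    fit_ebayes,
    pairwise_moderated_de,
    preferential_scores,
    quantile_normalize,
    threshold_sweep,
)


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        m = pd.DataFrame({"c1": [1.0, 2.0, 3.0], "c2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["c1"].tolist() == [2.5, 3.5, 4.5]
        assert out["c2"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_rank_equivariance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        out = quantile_normalize(m)
        perm = rng.permutation(30)
        m2 = m.copy()
        m2["b"] = m["b"].to_numpy()[perm]
        out2 = quantile_normalize(m2)
        assert out2["a"].tolist() == out["a"].tolist()
        assert out2["b"].tolist() == out["b"].to_numpy()[perm].tolist()

    def test_ties_averaged(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 9.0]})
        out = quantile_normalize(m)
        assert out.loc[0, "a"] == out.loc[1, "a"]

    def test_single_column_warns(self):
        with pytest.warns(UserWarning):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestCollapse:
    def test_max_mean_kept_and_ties(self):
        m = pd.DataFrame(
            {
                "s1": [5.0, 7.0, 4.0, 4.0, 1.0],
                "s2": [5.0, 7.0, 4.0, 4.0, 1.0],
            },
            index=["tx1", "tx2", "tx3a", "tx3b", "unmapped"],
        )
        t2g = pd.Series(
            {"tx1": "geneA", "tx2": "geneA", "tx3a": "geneB", "tx3b": "geneB"}
        )
        out = collapse_to_genes(m, t2g)
        assert list(out.index) == ["geneA", "geneB"]
        assert out.loc["geneA", "s1"] == 7.0  # mean-7 transcript wins
        # tie at equal means: lexicographically smaller transcript id (tx3a)
        assert out.loc["geneB", "s1"] == 4.0

    def test_single_transcript_identity(self):
        m = pd.DataFrame({"s": [1.0]}, index=["t1"])
        out = collapse_to_genes(m, pd.Series({"t1": "g"}))
        assert out.loc["g", "s"] == 1.0


# limma oracle, frozen from a single Rscript run (see module docstring):
# 30 genes, tissues ta/tb/tc x 3 replicates, seeded generation below.
LIMMA_D0 = 32.30166
LIMMA_S0SQ = 0.2216586
LIMMA_T_TA_TB = [4.232943, 5.058711, 6.332492, 6.086886, 6.13353]
LIMMA_P_TA_TB = [1.390826e-04, 1.084871e-05, 1.928847e-07, 4.198962e-07, 3.621887e-07]
LIMMA_COEF_TA_TB = [1.594844, 1.975439, 2.444881, 2.260501, 2.476769]


def _oracle_atlas():
    rng = np.random.default_rng(7)
    genes = [f"g{i:02d}" for i in range(30)]
    tissues = ["ta", "tb", "tc"]
    samples = [f"{t}_r{r}" for t in tissues for r in (1, 2, 3)]
    base = rng.normal(8, 1, 30)
    X = base[:, None] + rng.normal(0, 0.5, (30, 9))
    X[:5, :3] += 2.0
    matrix = pd.DataFrame(X, index=genes, columns=samples)
    sample_map = pd.Series([s.split("_")[0] for s in samples], index=samples)
    return ExpressionAtlas(matrix=matrix, sample_map=sample_map)


class TestEBayes:
    def test_identical_variances_degenerate(self):
        from scipy import special

        eb = fit_ebayes(np.full(100, 0.25), d=6)
        assert eb.d0 == pytest.approx(1e6)
        # zero spread -> point-mass prior at exp(mean e); the log-scale
        # bias correction exp(log(d/2) - digamma(d/2)) stays in place
        expected = 0.25 * np.exp(np.log(3.0) - special.digamma(3.0))
        assert eb.s0_sq == pytest.approx(expected, rel=1e-9)
        post = eb.posterior_variance(np.full(5, 0.25), 6)
        assert post == pytest.approx(eb.s0_sq, rel=1e-3)

    def test_posterior_between_prior_and_estimate(self):
        rng = np.random.default_rng(1)
        s2 = 0.05 * 4 / rng.chisquare(4, 500) * rng.chisquare(6, 500) / 6
        eb = fit_ebayes(s2, d=6)
        post = eb.posterior_variance(s2, 6)
        lo = np.minimum(s2, eb.s0_sq)
        hi = np.maximum(s2, eb.s0_sq)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_matches_limma_oracle(self):
        de = pairwise_moderated_de(_oracle_atlas())
        assert de.ebayes.d0 == pytest.approx(LIMMA_D0, rel=1e-5)
        assert de.ebayes.s0_sq == pytest.approx(LIMMA_S0SQ, rel=1e-5)
        ia, ib = de.tissues.index("ta"), de.tissues.index("tb")
        assert de.beta[:5, ia, ib] == pytest.approx(LIMMA_COEF_TA_TB, rel=1e-5)
        assert de.tstat[:5, ia, ib] == pytest.approx(LIMMA_T_TA_TB, rel=1e-5)
        assert de.pvalue[:5, ia, ib] == pytest.approx(LIMMA_P_TA_TB, rel=1e-4)

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            fit_ebayes([0.1], d=4)


class TestPairwiseDE:
    def test_beta_is_mean_difference(self):
        genes = ["g"]
        samples = [f"{t}_r{r}" for t in ("a", "b") for r in (1, 2, 3)]
        matrix = pd.DataFrame(
            [[5.0, 5.1, 4.9, 3.0, 3.1, 2.9]], index=genes, columns=samples
        )
        sm = pd.Series(["a"] * 3 + ["b"] * 3, index=samples)
        de = pairwise_moderated_de(
            ExpressionAtlas(matrix=pd.concat([matrix] * 3), sample_map=sm)
        )
        ia, ib = de.tissues.index("a"), de.tissues.index("b")
        assert de.beta[0, ia, ib] == pytest.approx(2.0)

    def test_antisymmetry(self, small_atlas):
        de = pairwise_moderated_de(small_atlas)
        assert np.allclose(de.beta, -de.beta.transpose(0, 2, 1), atol=1e-14)
        assert np.allclose(de.pvalue, de.pvalue.transpose(0, 2, 1), atol=1e-14)

    def test_d0_zero_is_ordinary_t(self):
        atlas = _oracle_atlas()
        de = pairwise_moderated_de(atlas, d0_override=0.0)
        # ordinary pooled-variance t computed directly
        X = atlas.matrix.to_numpy()
        groups = [X[:, :3], X[:, 3:6], X[:, 6:]]
        means = np.stack([g.mean(axis=1) for g in groups], axis=1)
        rss = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means.T))
        s2 = rss / 6
        t_manual = (means[:, 0] - means[:, 1]) / np.sqrt(s2 * (1 / 3 + 1 / 3))
        ia, ib = de.tissues.index("ta"), de.tissues.index("tb")
        assert np.max(np.abs(de.tstat[:, ia, ib] - t_manual)) < 1e-10

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i:04d}" for i in range(2000)]
        samples = [f"{t}_r{r}" for t in ("a", "b", "c") for r in (1, 2, 3)]
        matrix = pd.DataFrame(
            rng.normal(8, 1, (2000, 9)), index=genes, columns=samples
        )
        sm = pd.Series([s.split("_")[0] for s in samples], index=samples)
        de = pairwise_moderated_de(ExpressionAtlas(matrix=matrix, sample_map=sm))
        from scipy import stats

        ia, ib = 0, 1
        ks = stats.kstest(de.pvalue[:, ia, ib], "uniform")
        assert ks.pvalue > 0.01

    def test_insufficient_residual_df(self):
        samples = ["a_r1", "b_r1"]
        matrix = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=samples)
        sm = pd.Series(["a", "b"], index=samples)
        with pytest.raises(ValueError, match="residual df"):
            pairwise_moderated_de(ExpressionAtlas(matrix=matrix, sample_map=sm))


class TestScoresAndCalls:
    def test_bonferroni_threshold_27_tissues(self):
        assert 0.05 / 26 == pytest.approx(0.0019, abs=5e-5)

    def test_score_properties(self, small_atlas):
        de = pairwise_moderated_de(small_atlas)
        scores = preferential_scores(de)
        assert scores.abs().max().max() <= 1.0 + 1e-12
        assert scores.abs().max().max() == pytest.approx(1.0)  # extreme attained
        assert scores.loc["g1", "a"] == pytest.approx(1.0)

    def test_no_significant_gives_zero(self):
        rng = np.random.default_rng(0)
        samples = [f"{t}_r{r}" for t in ("a", "b") for r in (1, 2, 3)]
        matrix = pd.DataFrame(
            rng.normal(0, 1, (10, 6)), index=[f"g{i}" for i in range(10)], columns=samples
        )
        sm = pd.Series(["a"] * 3 + ["b"] * 3, index=samples)
        de = pairwise_moderated_de(ExpressionAtlas(matrix=matrix, sample_map=sm))
        scores = preferential_scores(de, family_alpha=1e-12)
        assert (scores == 0).all().all()

    def test_call_strictness(self):
        scores = pd.DataFrame({"t": [0.100, 0.1000001, -0.5]}, index=list("abc"))
        calls = call_preferential(scores, 0.1)
        assert calls["t"].tolist() == [0, 1, 0]

    def test_threshold_zero(self):
        scores = pd.DataFrame({"t": [0.0, 0.01, -0.01]}, index=list("abc"))
        assert call_preferential(scores, 0.0)["t"].tolist() == [0, 1, 0]

    def test_sweep_monotone(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.uniform(-1, 1, (20, 4)))
        sweep = threshold_sweep(scores, [0.05, 0.1, 0.3])
        prev = None
        for t in sorted(sweep):
            total = sweep[t].to_numpy()
            if prev is not None:
                assert np.all(total <= prev)
            prev = total

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_preferential(pd.DataFrame({"t": [0.5]}), 1.0)


def test_scorer_estimator(small_atlas):
    # QN across only 4 genes distorts the toy signal; score the raw matrix
    est = PreferentialExpressionScorer(quantile_norm=False).fit(small_atlas)
    assert est.scores_.shape == (4, 2)
    assert est.calls_.loc["g1", "a"] == 1
    assert est.transform(small_atlas).equals(est.scores_)
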
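"""MRF factor estimation, partition function and tissue significance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from prizenet import (
    configuration_score,
    estimate_factors,
    partition_function,
    resampled_subnetwork_test,
    tissue_permutation_test,
)
from prizenet.mrf import EdgeFactorTable, TissueMRFScorer, _log_z_enumerate, _log_z_tree


def calls_frame(rows, genes=None, tissues=None):
    rows = np.asarray(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    tissues = tissues or [f"t{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=tissues)


def uniform_factors(edges, T=4, value=1.0):
    return EdgeFactorTable(
        factors={e: np.full((2, 2), float(value)) for e in edges},
        n_tissues=T,
        epsilon=0.0,
    )


def enumeration_z(factors):
    """Independent brute-force partition function."""
    nodes = factors.nodes
    total = 0.0
    for config in itertools.product((0, 1), repeat=len(nodes)):
        x = dict(zip(nodes, config))
        prod = 1.0
        for i, j in factors.edges:
            prod *= factors.phi(i, j, x[i], x[j])
        total += prod
    return total


class TestEstimateFactors:
    def test_direct_counting(self):
        calls = calls_frame([[1, 1, 0, 0], [1, 0, 1, 0]], genes=["i", "j"])
        tab = estimate_factors(calls, [("i", "j")], epsilon=0.0)
        assert np.allclose(tab.factors[("i", "j")], np.ones((2, 2)))

    def test_sum_equals_n_tissues(self):
        rng = np.random.default_rng(0)
        calls = calls_frame(rng.integers(0, 2, (4, 7)))
        tab = estimate_factors(calls, [("g0", "g1"), ("g1", "g2"), ("g2", "g3")])
        for f in tab.factors.values():
            assert f.sum() == pytest.approx(7.0)

    def test_smoothing_arithmetic(self):
        # counts (3,1,0,0), eps 0.5, T=4 -> (3.5,1.5,0.5,0.5) * 4/6
        calls = calls_frame([[1, 1, 1, 0], [1, 1, 1, 1]], genes=["i", "j"])
        # (x_i, x_j) across tissues: (1,1)x3, (0,1)x1
        tab = estimate_factors(calls, [("i", "j")], epsilon=0.5)
        f = tab.factors[("i", "j")]
        assert f[1, 1] == pytest.approx(3.5 * 4 / 6)
        assert f[0, 1] == pytest.approx(1.5 * 4 / 6)
        assert f[0, 0] == pytest.approx(0.5 * 4 / 6)
        assert f[1, 0] == pytest.approx(0.5 * 4 / 6)

    def test_missing_gene_named(self):
        calls = calls_frame([[1, 0]], genes=["i"])
        with pytest.raises(ValueError, match="ghost"):
            estimate_factors(calls, [("i", "ghost")])


class TestPartitionFunction:
    def test_single_edge_all_ones(self):
        assert partition_function(uniform_factors([("a", "b")])) == pytest.approx(4.0)

    def test_uniform_tree_closed_form(self):
        # Z = 2^n * c^m for constant factors c on a tree
        edges = [("a", "b"), ("b", "c"), ("b", "d"), ("d", "e")]
        z = partition_function(uniform_factors(edges, value=1.7))
        assert z == pytest.approx(2**5 * 1.7**4)

    def test_sum_product_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            parents = [int(rng.integers(0, k)) for k in range(1, n)]
            edges = [(f"n{p}", f"n{k + 1}") for k, p in enumerate(parents)]
            tab = EdgeFactorTable(
                factors={
                    tuple(sorted(e)): rng.uniform(0.1, 5.0, (2, 2)) for e in edges
                },
                n_tissues=8,
                epsilon=0.0,
            )
            z_sp = np.exp(_log_z_tree(tab))
            assert z_sp == pytest.approx(enumeration_z(tab), rel=1e-12)
            assert np.exp(_log_z_enumerate(tab)) == pytest.approx(z_sp, rel=1e-10)

    def test_cycle_uses_enumeration(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a")]
        tab = uniform_factors(edges, value=2.0)
        assert partition_function(tab) == pytest.approx(enumeration_z(tab))

    def test_large_cycle_errors(self):
        nodes = [f"n{i:02d}" for i in range(25)]
        edges = [(nodes[i], nodes[(i + 1) % 25]) for i in range(25)]
        with pytest.raises(ValueError, match="enumeration"):
            partition_function(uniform_factors(edges), structure="general")


class TestConfigurationScore:
    def test_uniform_factors_uniform_probability(self):
        edges = [("a", "b"), ("b", "c")]
        tab = uniform_factors(edges)
        for config in itertools.product((0, 1), repeat=3):
            sc = configuration_score(dict(zip("abc", config)), tab)
            assert sc.probability == pytest.approx(1 / 8)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("b", "e")]
        tab = EdgeFactorTable(
            factors={tuple(sorted(e)): rng.uniform(0.2, 3.0, (2, 2)) for e in edges},
            n_tissues=6,
            epsilon=0.0,
        )
        total = sum(
            configuration_score(dict(zip("abcde", cfg)), tab).probability
            for cfg in itertools.product((0, 1), repeat=5)
        )
        assert total == pytest.approx(1.0)

    def test_concentrated_factor_maximizer(self):
        tab = EdgeFactorTable(
            factors={
                ("a", "b"): np.array([[0.1, 0.1], [0.1, 5.0]]),
                ("b", "c"): np.array([[0.1, 0.1], [0.1, 5.0]]),
            },
            n_tissues=6,
            epsilon=0.0,
        )
        probs = {
            cfg: configuration_score(dict(zip("abc", cfg)), tab).probability
            for cfg in itertools.product((0, 1), repeat=3)
        }
        assert max(probs, key=probs.get) == (1, 1, 1)

    def test_zero_factor_warns(self):
        calls = calls_frame([[1, 1], [1, 1]], genes=["i", "j"])
        tab = estimate_factors(calls, [("i", "j")], epsilon=0.0)
        with pytest.warns(UserWarning):
            sc = configuration_score({"i": 0, "j": 0}, tab)
        assert sc.probability == 0.0


class TestTissuePermutation:
    def test_deterministic(self):
        rng = np.random.default_rng(1)
        calls = calls_frame(rng.integers(0, 2, (5, 8)))
        edges = [("g0", "g1"), ("g1", "g2"), ("g2", "g3"), ("g3", "g4")]
        a = tissue_permutation_test(calls, edges, n_perm=25, seed=3)
        b = tissue_permutation_test(calls, edges, n_perm=25, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_tissue_most_significant(self):
        # coherent ON-state in tissue t0 for all genes, sparse elsewhere
        rng = np.random.default_rng(0)
        rows = (rng.random((6, 10)) < 0.1).astype(int)
        rows[:, 0] = 1
        calls = calls_frame(rows)
        edges = [(f"g{i}", f"g{i + 1}") for i in range(5)]
        rep = tissue_permutation_test(calls, edges, n_perm=100, seed=2)
        assert rep["permutation_p"].idxmin() == "t0"

    def test_pvalues_valid_range(self):
        rng = np.random.default_rng(9)
        calls = calls_frame(rng.integers(0, 2, (4, 6)))
        rep = tissue_permutation_test(
            calls, [("g0", "g1"), ("g1", "g2"), ("g2", "g3")], n_perm=19, seed=0
        )
        assert ((rep["permutation_p"] > 0) & (rep["permutation_p"] <= 1)).all()


class TestResampledTest:
    def test_observed_included_gives_r_at_least_one(self):
        rng = np.random.default_rng(4)
        calls = calls_frame(rng.integers(0, 2, (6, 8)))
        obs_edges = [("g0", "g1"), ("g1", "g2")]
        resampled = [obs_edges, [("g3", "g4"), ("g4", "g5")]]
        rep = resampled_subnetwork_test(calls, obs_edges, resampled)
        assert (rep["n_exceed"] >= 1).all()
        assert (rep["resampled_p"] <= 1).all()

    def test_empty_resampled_errors(self):
        calls = calls_frame([[1, 0], [0, 1]], genes=["a", "b"])
        with pytest.raises(ValueError):
            resampled_subnetwork_test(calls, [("a", "b")], [])


def test_scorer_estimator():
    rng = np.random.default_rng(8)
    rows = (rng.random((5, 9)) < 0.15).astype(int)
    rows[:, 4] = 1
    calls = calls_frame(rows)
    edges = [(f"g{i}", f"g{i + 1}") for i in range(4)]
    est = TissueMRFScorer(n_permutations=50, random_state=0).fit(
        calls, edges, resampled_edge_sets=[edges, edges[:2]]
    )
    assert est.report_["permutation_p"].idxmin() == "t4"
    assert "resampled_p" in est.report_.columns
    assert est.report_.loc["t4", "n_genes_called"] == 5
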
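"""Spearman matrices, the density statistic, and bootstrap edge filtering."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_block, spearman_oracle
from dietnet.correlation_networks import (
    bootstrap_network,
    compare_density,
    density_samples_to_frame,
    edges_to_frame,
    network_density,
    network_to_graphml,
    node_degree_profile,
    spearman_matrix,
    spearman_pair,
)
from dietnet.ffq_ingest import FOOD_GROUPS
from dietnet.synthetic_cohort import planted_target


class TestSpearmanPair:
    def test_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        rho, _ = spearman_pair(x, x)
        assert rho == pytest.approx(1.0)

    def test_reversal(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _ = spearman_pair(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        rho, _ = spearman_pair(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y))
        assert rho == pytest.approx(0.8)

    def test_zero_variance_not_computable(self):
        rho, p = spearman_pair(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)


class TestSpearmanMatrix:
    def test_duplicated_column_gives_unit_rho(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 14))
        X[:, 3] = X[:, 2]
        rho, p, p_adj = spearman_matrix(X)
        assert rho[2, 3] == pytest.approx(1.0)
        assert rho.shape == (14, 14)
        assert np.allclose(rho, rho.T, equal_nan=True)

    def test_adjusted_dominates_raw(self):
        rng = np.random.default_rng(1)
        _, p, p_adj = spearman_matrix(rng.normal(size=(60, 14)))
        iu = np.triu_indices(14, 1)
        assert np.all(p_adj[iu] >= p[iu] - 1e-12)

    def test_null_columns_rarely_significant(self):
        """Independent columns at n=500: Holm keeps family error near alpha."""
        hits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            _, _, p_adj = spearman_matrix(rng.normal(size=(500, 14)))
            iu = np.triu_indices(14, 1)
            hits.append(int(np.sum(p_adj[iu] < 0.05)))
        assert sorted(hits)[-1] <= 1 or np.mean([h == 0 for h in hits]) >= 0.9

    def test_degenerate_column_flagged_and_excluded(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 14))
        X[:, 5] = 7.0
        rho, p, p_adj = spearman_matrix(X)
        assert np.isnan(rho[5, 0]) and np.isnan(p_adj[5, 0])
        other = np.delete(np.delete(p_adj, 5, 0), 5, 1)
        iu = np.triu_indices(13, 1)
        assert not np.isnan(other[iu]).any()


class TestNetworkDensity:
    @pytest.mark.parametrize("L,N,expected", [
        (91, 14, 1.0),
        (0, 14, 0.0),
        (0, 5, 0.0),
        (13, 14, 13 / 91),
    ])
    def test_formula(self, L, N, expected):
        assert network_density(L, N) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            network_density(92, 14)
        with pytest.raises(ValueError):
            network_density(-1, 14)

    def test_matches_adjacency_edge_count_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            A = np.triu(rng.random((14, 14)) < 0.3, k=1)
            L = int(A.sum())
            assert network_density(L, 14) == pytest.approx(L / 91)


@pytest.fixture(scope="module")
def planted_run():
    """One bootstrap run with rho=+0.85 and -0.80 planted pairs (n=150)."""
    target = planted_target(0.0, {
        ("Sugar and sweets", "Sweetened beverages"): 0.85,
        ("Vegetables", "Fast food"): -0.80,
    })
    rng = np.random.default_rng(99)
    block = make_block(rng, 150, target)
    return bootstrap_network(block, stratum="plant", B=100, seed=7)


class TestBootstrapNetwork:
    def test_planted_edges_recovered_with_signs(self, planted_run):
        net, _ = planted_run
        found = {(e.a, e.b): e.sign for e in net.edges}
        assert found.get(("Sugar and sweets", "Sweetened beverages")) == "positive"
        assert found.get(("Fast food", "Vegetables")) == "negative"
        assert len(net.edges) == 2

    def test_sign_matches_full_sample_rho(self, planted_run):
        net, _ = planted_run
        for e in net.edges:
            assert e.sign == ("positive" if e.rho_full > 0 else "negative")
            assert abs(e.rho_full) > 0.5 and e.support >= 0.5 and e.p_adj_full < 0.05

    def test_density_samples_shape_and_bounds(self, planted_run):
        _, samples = planted_run
        assert len(samples) == 100
        d = [s.density for s in samples]
        assert all(0.0 <= x <= 1.0 for x in d)
        assert all(0 <= s.L <= 91 and s.N == 14 for s in samples)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        block = make_block(rng, 60, planted_target(0.3))
        n1, s1 = bootstrap_network(block, B=20, seed=42)
        n2, s2 = bootstrap_network(block, B=20, seed=42)
        assert edges_to_frame(n1).equals(edges_to_frame(n2))
        assert density_samples_to_frame(s1).equals(density_samples_to_frame(s2))
        n3, _ = bootstrap_network(block, B=20, seed=43)
        assert (not edges_to_frame(n1).equals(edges_to_frame(n3))
                or [e.support for e in n1.edges] != [e.support for e in n3.edges])

    def test_filter_monotonicity(self):
        """Raising rho_min or support_min never adds edges."""
        rng = np.random.default_rng(6)
        block = make_block(rng, 120, planted_target(0.45))
        base, _ = bootstrap_network(block, B=30, seed=1)
        pairs = {(e.a, e.b) for e in base.edges}
        for kwargs in ({"rho_min": 0.7}, {"support_min": 0.9},
                       {"rho_min": 0.6, "support_min": 0.8}):
            strict, _ = bootstrap_network(block, B=30, seed=1, **kwargs)
            assert {(e.a, e.b) for e in strict.edges} <= pairs

    def test_below_rho_min_never_included(self):
        """A planted rho=0.3 pair fails the deterministic |rho| filter."""
        target = planted_target(0.0, {("Meat", "Oils"): 0.3})
        rng = np.random.default_rng(12)
        block = make_block(rng, 400, target)
        net, _ = bootstrap_network(block, B=20, seed=3)
        assert ("Meat", "Oils") not in {(e.a, e.b) for e in net.edges}

    def test_b_one_binary_support(self):
        rng = np.random.default_rng(8)
        block = make_block(rng, 50, planted_target(0.6))
        net, samples = bootstrap_network(block, B=1, seed=0)
        assert len(samples) == 1
        assert all(e.support in (0.0, 1.0) for e in net.edges)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(9)
        block = make_block(rng, 10, planted_target(0.0))
        with pytest.raises(ValueError, match="at least"):
            bootstrap_network(block, B=5, seed=0)


class TestCompareDensity:
    def test_identical_strata_not_significant(self):
        from dietnet.correlation_networks import DensitySample

        samples = {
            s: [DensitySample(s, b, 10, 14, 10 / 91) for b in range(1, 21)]
            for s in ("a", "b")
        }
        h, p, dunn = compare_density(samples)
        assert h == pytest.approx(0.0)
        assert np.allclose(dunn["p_adj"], 1.0)

    def test_dense_vs_independent_strata_detected(self):
        rng = np.random.default_rng(30)
        dense = make_block(rng, 150, planted_target(0.6))
        indep = make_block(rng, 150, planted_target(0.0))
        _, s_dense = bootstrap_network(dense, stratum="dense", B=50, seed=1)
        _, s_indep = bootstrap_network(indep, stratum="indep", B=50, seed=2)
        _, p, _ = compare_density({"dense": s_dense, "indep": s_indep})
        assert p < 0.01

    def test_single_stratum_rejected(self):
        from dietnet.correlation_networks import DensitySample

        with pytest.raises(ValueError):
            compare_density({"a": [DensitySample("a", 1, 0, 14, 0.0)]})


class TestNodeDegrees:
    def test_empty_and_single_edge_networks(self):
        from dietnet.correlation_networks import CorrelationEdge, StratumNetwork

        empty = StratumNetwork("e", tuple(FOOD_GROUPS), (), 30, 10, 0.05, 0.5, 0.5)
        assert set(empty.node_degree.values()) == {0}
        edge = CorrelationEdge("Fruits", "Meat", 0.8, 0.001, 1.0, "positive")
        one = StratumNetwork("o", tuple(FOOD_GROUPS), (edge,), 30, 10, 0.05, 0.5, 0.5)
        deg = one.node_degree
        assert deg["Fruits"] == deg["Meat"] == 1
        assert sum(deg.values()) == 2
        prof = node_degree_profile({"e": empty, "o": one})
        assert prof.loc["Fruits", "o"] == 1 and prof.loc["Fruits", "e"] == 0

    def test_hub_attains_max_degree(self):
        """A food group correlated with four others becomes the top node."""
        hub_pairs = {("Meat", g): 0.85 for g in
                     ("Fruits", "Oils", "Roots", "Coffee")}
        rng = np.random.default_rng(44)
        block = make_block(rng, 200, planted_target(0.0, hub_pairs))
        net, _ = bootstrap_network(block, B=50, seed=5)
        deg = net.node_degree
        assert deg["Meat"] == max(deg.values()) >= 3

    def test_degrees_sum_to_twice_edges(self, planted_run):
        net, _ = planted_run
        assert sum(net.node_degree.values()) == 2 * len(net.edges)
        assert net.positive_count + net.negative_count == len(net.edges)


def test_graphml_roundtrip(tmp_path, planted_run):
    import networkx as nx

    net, _ = planted_run
    path = tmp_path / "net.graphml"
    network_to_graphml(net, path)
    G = nx.read_graphml(path)
    assert G.number_of_nodes() == 14
    assert G.number_of_edges() == len(net.edges)
    for _, _, data in G.edges(data=True):
        assert data["sign"] in ("positive", "negative")
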
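"""Graph metrics against hand-worked examples and brute-force oracles."""

import numpy as np
import pytest

import oracles

from netrel.graphmetrics import (NullModelConfig, assortativity,
                                 characteristic_path_length,
                                 clustering_coefficient, correlation_null,
                                 global_efficiency, global_metrics,
                                 hierarchy_beta, local_efficiency,
                                 metric_curves, modularity, modularity_q,
                                 nodal_betweenness, nodal_degree,
                                 nodal_efficiency, normalized_smallworld,
                                 rewire_null)
from netrel.networks import (BinaryNetwork, ConnectivityMatrix, SparsityGrid,
                             correlation_matrix, round_half_away,
                             sparsity_sweep)


def _net(edges, n):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(adj, adj.sum() / (n * (n - 1)))


TRIANGLE = _net([(0, 1), (1, 2), (0, 2)], 3)
PATH3 = _net([(0, 1), (1, 2)], 3)
STAR4 = _net([(0, 1), (0, 2), (0, 3), (0, 4)], 5)   # hub 0, 4 leaves
K4 = _net([(i, j) for i in range(4) for j in range(i + 1, 4)], 4)


def test_clustering_hand_examples():
    c, cp = clustering_coefficient(TRIANGLE)
    assert np.allclose(c, 1.0) and cp == 1.0
    c, cp = clustering_coefficient(_net([(0, 1), (0, 2), (0, 3)], 4))
    assert np.allclose(c, 0.0) and cp == 0.0    # star: no neighbor links


def test_path_length_hand_examples():
    assert characteristic_path_length(TRIANGLE) == 1.0
    assert characteristic_path_length(PATH3) == pytest.approx(4.0 / 3.0)
    with pytest.raises(ValueError, match="reachable"):
        characteristic_path_length(_net([], 4))


def test_efficiency_hand_examples():
    assert global_efficiency(K4) == 1.0
    assert np.allclose(nodal_efficiency(K4), 1.0)
    assert global_efficiency(PATH3) == pytest.approx(5.0 / 6.0)
    assert nodal_efficiency(PATH3)[0] == pytest.approx(0.75)
    assert local_efficiency(K4) == 1.0          # every neighbor subgraph = K3
    assert local_efficiency(STAR4) == 0.0


def test_degree_and_betweenness_hand_examples():
    assert list(nodal_degree(K4)) == [3, 3, 3, 3]
    assert list(nodal_degree(STAR4)) == [4, 1, 1, 1, 1]
    assert list(nodal_betweenness(PATH3)) == [0.0, 1.0, 0.0]
    assert list(nodal_betweenness(STAR4)) == [6.0, 0, 0, 0, 0]  # C(4,2)


@pytest.mark.parametrize("seed", range(12))
def test_metrics_match_brute_force_oracles(seed):
    """Cp, Lp, Eglob, Eloc, nodal efficiency, degree and betweenness agree
    with exhaustive pure-Python enumeration on random <=7-node graphs."""
    rng = np.random.default_rng(seed)
    import random
    pyrng = random.Random(seed)
    n = pyrng.choice([4, 5, 6, 7])
    adj_list = oracles.random_adjacency(pyrng, n, pyrng.uniform(0.25, 0.8))
    net = BinaryNetwork(np.array(adj_list, dtype=np.uint8), 0.5)
    del rng

    c, cp = clustering_coefficient(net)
    oc, ocp = oracles.bf_clustering(adj_list)
    assert np.allclose(c, oc) and cp == pytest.approx(ocp)

    try:
        expected_lp = oracles.bf_path_length(adj_list)
        assert characteristic_path_length(net) == pytest.approx(expected_lp)
    except ValueError:
        with pytest.raises(ValueError):
            characteristic_path_length(net)

    assert global_efficiency(net) == pytest.approx(
        oracles.bf_global_efficiency(adj_list))
    assert np.allclose(nodal_efficiency(net),
                       oracles.bf_nodal_efficiency(adj_list))
    assert local_efficiency(net) == pytest.approx(
        oracles.bf_local_efficiency(adj_list))
    assert list(nodal_degree(net)) == oracles.bf_degree(adj_list)
    assert sum(nodal_degree(net)) == 2 * net.n_edges    # handshake
    assert np.allclose(nodal_betweenness(net),
                       oracles.bf_betweenness(adj_list), atol=1e-9)


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def test_single_module_partition_has_zero_q():
    for net in (TRIANGLE, K4, STAR4):
        labels = np.zeros(net.n_nodes, dtype=int)
        assert modularity_q(net, labels) == pytest.approx(0.0)


def test_two_cliques_modularity():
    adj = np.zeros((8, 8), dtype=np.uint8)
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    adj[i, j] = 1
    q, labels = modularity(adj)
    assert q == pytest.approx(0.5)
    assert len(np.unique(labels)) == 2
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    # exhaustive partition search confirms 0.5 is optimal
    best_q, _ = oracles.bf_best_modularity([list(r) for r in adj])
    assert best_q == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(6))
def test_greedy_q_bounded_by_exhaustive_optimum(seed):
    import random
    pyrng = random.Random(seed)
    adj_list = oracles.random_adjacency(pyrng, 7, 0.4)
    if sum(map(sum, adj_list)) == 0:
        return
    q, labels = modularity(np.array(adj_list, dtype=np.uint8))
    best_q, _ = oracles.bf_best_modularity(adj_list)
    assert q <= best_q + 1e-9
    if best_q > 1e-9:
        assert q >= 0.0          # never worse than the single-module split
    # returned Q is exactly the closed-form Q of the returned partition
    assert q == pytest.approx(
        oracles.bf_modularity_q(adj_list,
                                [list(np.flatnonzero(labels == m))
                                 for m in np.unique(labels)]))


def test_modularity_edgeless_rejected():
    with pytest.raises(ValueError, match="edgeless"):
        modularity(np.zeros((4, 4), dtype=np.uint8))


# ---------------------------------------------------------------------------
# hierarchy + assortativity
# ---------------------------------------------------------------------------

def test_hierarchy_regular_ring_undefined():
    ring = _net([(i, (i + 1) % 6) for i in range(6)]
                + [(i, (i + 2) % 6) for i in range(6)], 6)
    assert len(np.unique(nodal_degree(ring))) == 1
    assert hierarchy_beta(ring) is None


@pytest.mark.parametrize("seed", range(8))
def test_hierarchy_matches_closed_form_slope(seed):
    import random
    pyrng = random.Random(seed)
    adj_list = oracles.random_adjacency(pyrng, 8, 0.5)
    net = np.array(adj_list, dtype=np.uint8)
    cs, _ = oracles.bf_clustering(adj_list)
    ks = oracles.bf_degree(adj_list)
    pairs = [(k, c) for k, c in zip(ks, cs) if k >= 2 and c > 0]
    beta = hierarchy_beta(net)
    if len(pairs) < 2 or len({k for k, _ in pairs}) < 2:
        assert beta is None
    else:
        slope = oracles.bf_hierarchy_slope(*zip(*pairs))
        assert beta == pytest.approx(-slope, abs=1e-10)


def test_assortativity_star_is_minus_one():
    assert assortativity(STAR4) == pytest.approx(-1.0)


def test_assortativity_regular_graph_undefined():
    assert assortativity(K4) is None


@pytest.mark.parametrize("seed", range(8))
def test_assortativity_matches_edge_list_pearson(seed):
    import random
    pyrng = random.Random(seed)
    adj_list = oracles.random_adjacency(pyrng, 8, 0.4)
    expected = oracles.bf_assortativity(adj_list)
    got = assortativity(np.array(adj_list, dtype=np.uint8))
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------

def test_rewired_nulls_preserve_degree_sequence(rng):
    import networkx as nx
    g = nx.gnm_random_graph(30, 90, seed=3)
    net = BinaryNetwork(nx.to_numpy_array(g, dtype=np.uint8), 0.2)
    nulls = rewire_null(net, NullModelConfig(n_null=10, swaps_per_edge=10,
                                             seed=1))
    for nn in nulls:
        assert np.array_equal(nodal_degree(nn), nodal_degree(net))
        assert np.array_equal(nn.adjacency, nn.adjacency.T)
        assert not nn.adjacency.diagonal().any()
    # the ensemble actually randomizes something
    assert any(not np.array_equal(nn.adjacency, net.adjacency)
               for nn in nulls)


def test_complete_graph_returns_copies_with_warning():
    k5 = _net([(i, j) for i in range(5) for j in range(i + 1, 5)], 5)
    with pytest.warns(RuntimeWarning, match="complete"):
        nulls = rewire_null(k5, NullModelConfig(n_null=3, swaps_per_edge=5,
                                                seed=0))
    assert all(np.array_equal(nn.adjacency, k5.adjacency) for nn in nulls)


def test_lattice_clustering_destroyed_by_rewiring():
    import networkx as nx
    lattice = nx.watts_strogatz_graph(60, 6, 0.0, seed=0)   # pure ring lattice
    net = BinaryNetwork(nx.to_numpy_array(lattice, dtype=np.uint8), 0.1)
    _, cp_lattice = clustering_coefficient(net)
    nulls = rewire_null(net, NullModelConfig(n_null=20, swaps_per_edge=10,
                                             seed=2))
    cp_null = np.mean([clustering_coefficient(nn)[1] for nn in nulls])
    assert cp_null < cp_lattice


def test_correlation_null_contract(rng):
    ts = rng.standard_normal((20, 400))
    ts += 0.8 * ts.mean(axis=0, keepdims=True)   # induce positive mean r
    cm = correlation_matrix(ts)
    cfg = NullModelConfig(method="correlation_randomization", n_null=100,
                          seed=4)
    nulls = correlation_null(cm, cfg)
    iu = np.triu_indices(20, k=1)
    mu, var = cm.values[iu].mean(), cm.values[iu].var()
    mus = np.mean([nc.values[iu].mean() for nc in nulls])
    vars_ = np.mean([nc.values[iu].var() for nc in nulls])
    assert abs(mus - mu) / mu < 0.05
    assert abs(vars_ - var) / var < 0.05
    for nc in nulls[:10]:
        assert np.allclose(nc.values, nc.values.T)
        assert np.allclose(np.diag(nc.values), 1.0)
        assert np.linalg.eigvalsh(nc.values).min() >= -1e-8


def test_correlation_null_identity_input():
    cfg = NullModelConfig(method="correlation_randomization", n_null=3)
    nulls = correlation_null(ConnectivityMatrix(np.eye(12)), cfg)
    assert all(np.allclose(nc.values, np.eye(12)) for nc in nulls)


def test_smallworld_gamma_centered_at_one_for_null_of_itself(rng):
    """Exchangeability: using a rewired null as the 'real' network gives a
    gamma distribution centred at 1."""
    import networkx as nx
    g = nx.gnm_random_graph(60, 360, seed=9)
    net = BinaryNetwork(nx.to_numpy_array(g, dtype=np.uint8), 0.2)
    gammas = []
    for s in range(8):
        base = rewire_null(net, NullModelConfig(n_null=1, swaps_per_edge=10,
                                                seed=100 + s))[0]
        gamma, _, _ = normalized_smallworld(
            base, NullModelConfig(n_null=12, swaps_per_edge=10, seed=s))
        gammas.append(gamma)
    assert np.mean(gammas) == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------------------
# metric curves
# ---------------------------------------------------------------------------

def test_metric_curves_shapes_and_degree_arithmetic(rng):
    cm = correlation_matrix(rng.standard_normal((46, 300)))
    grid = SparsityGrid((0.1, 0.2, 0.3))
    nets = sparsity_sweep(cm, grid)
    curves = metric_curves(nets)    # no nulls: gamma/lambda/sigma are NaN
    glob = curves[curves.node == "global"]
    assert len(glob) == 10 * 3
    for s in grid:
        deg = curves[(curves.metric == "degree") & (curves.sparsity == s)]
        assert deg.value.mean() == pytest.approx(
            2 * round_half_away(s * 1035) / 46)
    assert glob[glob.metric == "gamma"].value.isna().all()


def test_eglob_monotone_under_nesting(rng):
    cm = correlation_matrix(rng.standard_normal((20, 200)))
    nets = sparsity_sweep(cm, SparsityGrid(tuple(np.round(
        np.arange(0.05, 1.0, 0.05), 2))))
    eglobs = [global_efficiency(net) for net in nets]
    assert all(b >= a - 1e-12 for a, b in zip(eglobs, eglobs[1:]))


def test_sigma_equals_gamma_over_lambda(rng):
    import networkx as nx
    ws = nx.watts_strogatz_graph(60, 6, 0.1, seed=5)
    net = BinaryNetwork(nx.to_numpy_array(ws, dtype=np.uint8), 0.1)
    gamma, lam, sigma = normalized_smallworld(
        net, NullModelConfig(n_null=20, swaps_per_edge=10, seed=3))
    assert sigma == pytest.approx(gamma / lam)
    out = global_metrics(net,
                         NullModelConfig(n_null=5, swaps_per_edge=5, seed=3))
    assert set(out) >= {"Cp", "Lp", "gamma", "lambda", "sigma", "Eloc",
                        "Eglob", "Q", "beta", "r"}
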
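"""Global and nodal graph metrics on binary undirected networks.

Ten global measures — clustering coefficient Cp, characteristic path length
Lp, their null-normalized forms gamma and lambda, small-worldness
sigma = gamma/lambda, local and global efficiency, modularity Q, hierarchy
beta and assortativity r — plus three nodal measures (degree, efficiency,
betweenness), evaluated across a sparsity sweep.

Conventions (all switchable where noted):

* nodes with degree < 2 get clustering coefficient 0 (keeps Cp defined at
  sparse thresholds);
* Lp averages shortest path lengths over *reachable* pairs only; a network
  with no finite pair raises;
* efficiency treats disconnected pairs as contributing 0 (1/infinity);
* betweenness counts unordered pairs without endpoint normalization;
* the modularity partition comes from a deterministic greedy agglomeration
  (max-gain merge, lexicographic tie-break) so repeated runs are bit-stable.

Two null models normalize the small-world quantities: degree-preserving
Maslov–Sneppen rewiring, and a moment-matched random-correlation-matrix
scheme (Hirschberger–Qi–Steuer style) that preserves the transitive
structure correlation matrices impose on their thresholded graphs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .networks import BinaryNetwork, ConnectivityMatrix, threshold_by_sparsity

__all__ = [
    "NullModelConfig",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "local_efficiency",
    "nodal_degree",
    "nodal_betweenness",
    "modularity",
    "modularity_q",
    "hierarchy_beta",
    "assortativity",
    "rewire_null",
    "correlation_null",
    "normalized_smallworld",
    "global_metrics",
    "metric_curves",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("Cp", "Lp", "gamma", "lambda", "sigma",
                  "Eloc", "Eglob", "Q", "beta", "r")
NODAL_METRICS = ("degree", "efficiency", "betweenness")


def _adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    a = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return a.astype(np.uint8)


def _distances(adj: np.ndarray) -> np.ndarray:
    if adj.sum() == 0:
        n = adj.shape[0]
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(csr_matrix(adj), method="D", directed=False,
                         unweighted=True)


def _to_graph(adj: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(adj.shape[0]))
    g.add_edges_from(zip(*np.nonzero(np.triu(adj, k=1))))
    return g


def clustering_coefficient(net: BinaryNetwork | np.ndarray,
                           ) -> tuple[np.ndarray, float]:
    """Per-node clustering (triangles over possible neighbor pairs; 0 for
    degree-<2 nodes) and the network mean Cp."""
    adj = _adjacency(net).astype(float)
    k = adj.sum(axis=1)
    triangles = np.diag(adj @ adj @ adj) / 2.0
    denom = k * (k - 1) / 2.0
    c = np.zeros(adj.shape[0])
    mask = k >= 2
    c[mask] = triangles[mask] / denom[mask]
    return c, float(c.mean())


def characteristic_path_length(net: BinaryNetwork | np.ndarray) -> float:
    """Mean shortest path length over reachable unordered pairs."""
    d = _distances(_adjacency(net))
    iu = np.triu_indices(d.shape[0], k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("no reachable pair; path length undefined")
    return float(finite.mean())


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest path length (disconnected pairs contribute 0)."""
    d = _distances(_adjacency(net))
    n = d.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def nodal_efficiency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Per-node mean of 1/d(v, u) over all other nodes u."""
    d = _distances(_adjacency(net))
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / max(n - 1, 1)


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighbor-induced subgraph (0 for nodes with < 2 neighbors)."""
    adj = _adjacency(net)
    n = adj.shape[0]
    eff = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(adj[v])
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        eff[v] = global_efficiency(sub)
    return float(eff.mean())


def nodal_degree(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    return _adjacency(net).sum(axis=1).astype(int)


def nodal_betweenness(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Raw (unnormalized) betweenness over unordered pairs, Brandes-style."""
    adj = _adjacency(net)
    bc = nx.betweenness_centrality(_to_graph(adj), normalized=False)
    return np.array([bc[v] for v in range(adj.shape[0])])


def modularity_q(net: BinaryNetwork | np.ndarray, labels: np.ndarray) -> float:
    """Q = sum_m [l_m / L - (d_m / 2L)^2] for the given node partition."""
    adj = _adjacency(net).astype(float)
    total_edges = adj.sum() / 2.0
    if total_edges == 0:
        raise ValueError("modularity undefined for an edgeless network")
    q = 0.0
    for m in np.unique(labels):
        members = labels == m
        l_m = adj[np.ix_(members, members)].sum() / 2.0
        d_m = adj[members].sum()
        q += l_m / total_edges - (d_m / (2.0 * total_edges)) ** 2
    return float(q)


def modularity(net: BinaryNetwork | np.ndarray) -> tuple[float, np.ndarray]:
    """Deterministic greedy agglomerative modularity optimization.

    Starts from singleton communities and repeatedly merges the connected
    pair with the largest modularity gain (ties broken by the lexicographic
    order of the communities' smallest node labels) until no merge has a
    positive gain. Returns (Q, per-node community labels).
    """
    adj = _adjacency(net).astype(float)
    n = adj.shape[0]
    total_edges = adj.sum() / 2.0
    if total_edges == 0:
        raise ValueError("modularity undefined for an edgeless network")

    members: list[set[int]] = [{v} for v in range(n)]
    e_between = adj.copy()                    # edges between communities
    d_sum = adj.sum(axis=1)                   # degree sums per community
    reps = list(range(n))                     # smallest node label, tie-break
    active = list(range(n))

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            i = active[ai]
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                if e_between[i, j] == 0:
                    continue
                gain = (e_between[i, j] / total_edges
                        - d_sum[i] * d_sum[j] / (2.0 * total_edges ** 2))
                key = (-gain, min(reps[i], reps[j]), max(reps[i], reps[j]))
                if best is None or key < best[0]:
                    best = (key, i, j, gain)
        if best is None or best[3] <= 1e-12:
            break
        _, i, j, _ = best
        members[i] |= members[j]
        e_between[i, :] += e_between[j, :]
        e_between[:, i] += e_between[:, j]
        d_sum[i] += d_sum[j]
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    labels = np.empty(n, dtype=int)
    for new_label, i in enumerate(sorted(active, key=lambda c: reps[c])):
        for v in members[i]:
            labels[v] = new_label
    return modularity_q(adj, labels), labels


def hierarchy_beta(net: BinaryNetwork | np.ndarray) -> float | None:
    """beta from C(v) ~ k(v)^(-beta): minus the OLS slope of log C vs log k
    over nodes with degree >= 2 and C > 0. None when the regression is
    degenerate (fewer than two eligible nodes or no degree variation)."""
    adj = _adjacency(net)
    c, _ = clustering_coefficient(adj)
    k = nodal_degree(adj)
    mask = (k >= 2) & (c > 0)
    if mask.sum() < 2 or len(np.unique(k[mask])) < 2:
        return None
    slope = np.polyfit(np.log(k[mask]), np.log(c[mask]), 1)[0]
    return float(-slope)


def assortativity(net: BinaryNetwork | np.ndarray) -> float | None:
    """Degree–degree Pearson correlation over edges (Newman's r).

    None when undefined (degree variance over edge endpoints is zero)."""
    adj = _adjacency(net)
    if adj.sum() / 2 < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = nx.degree_pearson_correlation_coefficient(_to_graph(adj))
    return None if np.isnan(r) else float(r)


@dataclass(frozen=True)
class NullModelConfig:
    """Randomization scheme for the small-world normalization."""

    method: str = "topology_rewiring"   # or "correlation_randomization"
    n_null: int = 100
    swaps_per_edge: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.swaps_per_edge < 1:
            raise ValueError("swaps_per_edge must be >= 1")
        if self.method not in ("topology_rewiring",
                               "correlation_randomization"):
            raise ValueError(f"unknown null-model method {self.method!r}")


def _rewire_once(adj: np.ndarray, edges: np.ndarray, attempts: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Maslov–Sneppen double-edge swaps in place; returns (adj, n_swapped)."""
    n_edges = len(edges)
    swapped = 0
    pair_idx = rng.integers(0, n_edges, size=(attempts, 2))
    flips = rng.integers(0, 2, size=attempts)
    for t in range(attempts):
        e1, e2 = pair_idx[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flips[t]:
            c, d = d, c
        # propose (a, b), (c, d) -> (a, d), (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = (a, d)
        edges[e2] = (c, b)
        swapped += 1
    return adj, swapped


def rewire_null(net: BinaryNetwork, config: NullModelConfig,
                ) -> list[BinaryNetwork]:
    """Degree-preserving randomized surrogates of ``net``.

    Each null attempts ``swaps_per_edge * n_edges`` double-edge swaps. The
    degree sequence of every output equals the original exactly. A complete
    graph admits no valid swap; copies are returned with a warning.
    """
    adj0 = _adjacency(net)
    n = adj0.shape[0]
    edges0 = np.column_stack(np.nonzero(np.triu(adj0, k=1)))
    rng = np.random.default_rng(config.seed)
    attempts = config.swaps_per_edge * max(len(edges0), 1)
    nulls = []
    total_swapped = 0
    for _ in range(config.n_null):
        adj, swapped = _rewire_once(adj0.copy(), edges0.copy(), attempts, rng)
        total_swapped += swapped
        nulls.append(BinaryNetwork(adj, net.sparsity))
    if total_swapped == 0 and len(edges0) == n * (n - 1) // 2:
        warnings.warn("complete graph admits no degree-preserving swap; "
                      "returning copies", RuntimeWarning, stacklevel=2)
    return nulls


def correlation_null(cm: ConnectivityMatrix, config: NullModelConfig,
                     ) -> list[ConnectivityMatrix]:
    """Random correlation matrices matching the input's off-diagonal mean
    and variance (Hirschberger–Qi–Steuer-style factor construction).

    Each null is ``R = D^{-1/2} W W^T D^{-1/2}`` with W an n x m matrix of
    iid N(nu, delta^2) entries, nu^2 = mu/m and delta^2 = (1 - mu)/m, which
    targets a unit diagonal and off-diagonal mean mu. The normalization by
    the realized diagonal removes part of the raw variance (c_ij co-varies
    with c_ii); to first order the post-normalization off-diagonal variance
    is (1 - mu^4 - 4 mu^2 + 4 mu^3) / m, so m is rounded from that relation
    to hit the observed sigma^2. Outputs are exact correlation matrices
    (symmetric, unit diagonal, PSD). Thresholding them like real matrices
    preserves the transitive structure correlations impose.
    """
    values = cm.values
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    mu = float(values[iu].mean())
    sigma2 = float(values[iu].var())
    rng = np.random.default_rng(config.seed)

    if abs(mu) < 1e-12 and sigma2 < 1e-12:
        return [ConnectivityMatrix(np.eye(n)) for _ in range(config.n_null)]
    if mu <= 0.0 or mu >= 1.0:
        raise ValueError(f"off-diagonal mean {mu:.4f} infeasible for the "
                         "factor construction (need 0 < mean < 1)")
    if sigma2 <= 0.0:
        raise ValueError("zero off-diagonal variance with nonzero mean is "
                         "infeasible")
    post_var_per_factor = 1.0 - mu**4 - 4.0 * mu**2 + 4.0 * mu**3
    if post_var_per_factor <= 0.0:
        raise ValueError(f"off-diagonal mean {mu:.4f} infeasible for the "
                         "normalized factor construction")
    m = max(1, int(round(post_var_per_factor / sigma2)))
    nu = np.sqrt(mu / m)
    delta = np.sqrt((1.0 - mu) / m)
    nulls = []
    for _ in range(config.n_null):
        w = rng.normal(nu, delta, size=(n, m))
        c = w @ w.T
        d = np.sqrt(np.diag(c))
        r = c / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        nulls.append(ConnectivityMatrix(r, channel_ids=cm.channel_ids))
    return nulls


def normalized_smallworld(net: BinaryNetwork, config: NullModelConfig,
                          cm: ConnectivityMatrix | None = None,
                          ) -> tuple[float | None, float | None, float | None]:
    """(gamma, lambda, sigma) against the configured null ensemble.

    gamma = Cp / mean(Cp_null), lambda = Lp / mean(Lp_null), sigma =
    gamma/lambda. The correlation-randomization method requires the source
    ``cm`` to threshold nulls at the network's own sparsity. Undefined
    quantities (zero mean null clustering, no reachable pair) are None.
    """
    if config.method == "topology_rewiring":
        null_nets = rewire_null(net, config)
    else:
        if cm is None:
            raise ValueError("correlation_randomization needs the source "
                             "connectivity matrix")
        null_cms = correlation_null(cm, config)
        null_nets = [threshold_by_sparsity(nc, net.sparsity)
                     for nc in null_cms]

    _, cp_real = clustering_coefficient(net)
    cp_nulls = [clustering_coefficient(nn)[1] for nn in null_nets]
    lp_nulls = []
    for nn in null_nets:
        try:
            lp_nulls.append(characteristic_path_length(nn))
        except ValueError:
            continue
    try:
        lp_real = characteristic_path_length(net)
    except ValueError:
        lp_real = None

    cp_null_mean = float(np.mean(cp_nulls))
    gamma = cp_real / cp_null_mean if cp_null_mean > 0 else None
    lam = (lp_real / float(np.mean(lp_nulls))
           if lp_real is not None and lp_nulls else None)
    sigma = gamma / lam if gamma is not None and lam not in (None, 0) else None
    return gamma, lam, sigma


def global_metrics(net: BinaryNetwork, null_config: NullModelConfig | None = None,
                   cm: ConnectivityMatrix | None = None) -> dict[str, float]:
    """All ten global metrics; undefined values are NaN (never zero)."""
    out: dict[str, float] = {}
    _, out["Cp"] = clustering_coefficient(net)
    try:
        out["Lp"] = characteristic_path_length(net)
    except ValueError:
        out["Lp"] = np.nan
    out["Eloc"] = local_efficiency(net)
    out["Eglob"] = global_efficiency(net)
    try:
        out["Q"] = modularity(net)[0]
    except ValueError:
        out["Q"] = np.nan
    beta = hierarchy_beta(net)
    out["beta"] = np.nan if beta is None else beta
    r = assortativity(net)
    out["r"] = np.nan if r is None else r
    if null_config is not None:
        gamma, lam, sigma = normalized_smallworld(net, null_config, cm=cm)
        out["gamma"] = np.nan if gamma is None else gamma
        out["lambda"] = np.nan if lam is None else lam
        out["sigma"] = np.nan if sigma is None else sigma
    else:
        out["gamma"] = out["lambda"] = out["sigma"] = np.nan
    return out


def metric_curves(networks: list[BinaryNetwork],
                  null_config: NullModelConfig | None = None,
                  cm: ConnectivityMatrix | None = None) -> pd.DataFrame:
    """Evaluate every metric at every sparsity of a (nested) sweep.

    Returns a long-format frame with columns (metric, node, sparsity,
    value); global metrics carry node = "global". Undefined values are
    recorded as NaN. Null ensembles consume a per-sparsity derived seed so
    reruns are bit-stable regardless of evaluation order.
    """
    if not networks:
        raise ValueError("empty sparsity sweep")
    rows = []
    for net in networks:
        cfg = None
        if null_config is not None:
            derived = np.random.SeedSequence(
                null_config.seed,
                spawn_key=(int(round(net.sparsity * 1000)),),
            ).generate_state(1)[0] % (2**31)
            cfg = dataclasses.replace(null_config, seed=int(derived))
        gm = global_metrics(net, null_config=cfg, cm=cm)
        for metric in GLOBAL_METRICS:
            rows.append(("global", metric, net.sparsity, gm[metric]))
        deg = nodal_degree(net)
        eff = nodal_efficiency(net)
        btw = nodal_betweenness(net)
        for v in range(net.n_nodes):
            rows.append((str(v), "degree", net.sparsity, float(deg[v])))
            rows.append((str(v), "efficiency", net.sparsity, float(eff[v])))
            rows.append((str(v), "betweenness", net.sparsity, float(btw[v])))
    return pd.DataFrame(rows, columns=["node", "metric", "sparsity", "value"])
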
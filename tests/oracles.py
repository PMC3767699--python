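"""Independent brute-force oracles for small graphs.

Pure-Python enumeration (BFS dictionaries, neighbor-pair counting,
exhaustive shortest-path and partition enumeration) kept deliberately free
of the package's own numpy/scipy/networkx code paths.
"""

from __future__ import annotations

import itertools
from collections import deque


def neighbors(adj, v):
    return [u for u in range(len(adj)) if adj[v][u]]


def bf_distances(adj):
    """All-pairs BFS distances; None for unreachable."""
    n = len(adj)
    dist = [[None] * n for _ in range(n)]
    for s in range(n):
        dist[s][s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            for u in neighbors(adj, v):
                if dist[s][u] is None:
                    dist[s][u] = dist[s][v] + 1
                    queue.append(u)
    return dist


def bf_clustering(adj):
    n = len(adj)
    c = []
    for v in range(n):
        nbrs = neighbors(adj, v)
        k = len(nbrs)
        if k < 2:
            c.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a][b])
        c.append(links / (k * (k - 1) / 2))
    return c, sum(c) / n


def bf_path_length(adj):
    dist = bf_distances(adj)
    vals = [dist[i][j] for i in range(len(adj)) for j in range(i + 1, len(adj))
            if dist[i][j] is not None]
    if not vals:
        raise ValueError("no reachable pair")
    return sum(vals) / len(vals)


def bf_global_efficiency(adj):
    dist = bf_distances(adj)
    n = len(adj)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    total = sum(1.0 / dist[i][j] for i, j in pairs if dist[i][j])
    return total / len(pairs) if pairs else 0.0


def bf_nodal_efficiency(adj):
    dist = bf_distances(adj)
    n = len(adj)
    out = []
    for v in range(n):
        s = sum(1.0 / dist[v][u] for u in range(n)
                if u != v and dist[v][u])
        out.append(s / (n - 1))
    return out


def bf_local_efficiency(adj):
    n = len(adj)
    effs = []
    for v in range(n):
        nbrs = neighbors(adj, v)
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        effs.append(bf_global_efficiency(sub))
    return sum(effs) / n


def bf_degree(adj):
    return [sum(row) for row in adj]


def _all_shortest_paths(adj, src, dst):
    """Every shortest simple path from src to dst, by DFS with pruning."""
    dist = bf_distances(adj)
    if dist[src][dst] is None:
        return []
    target_len = dist[src][dst]
    paths = []

    def extend(path):
        v = path[-1]
        if v == dst:
            paths.append(tuple(path))
            return
        for u in neighbors(adj, v):
            if u in path or dist[u][dst] is None:
                continue
            # keep only extensions that stay on some shortest path
            if (len(path) - 1) + 1 + dist[u][dst] == target_len:
                extend(path + [u])

    extend([src])
    return paths


def bf_betweenness(adj):
    """Raw betweenness over unordered pairs via exhaustive shortest-path
    enumeration."""
    n = len(adj)
    bc = [0.0] * n
    for m, t in itertools.combinations(range(n), 2):
        paths = _all_shortest_paths(adj, m, t)
        if not paths:
            continue
        total = len(paths)
        for v in range(n):
            if v in (m, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / total
    return bc


def bf_assortativity(adj):
    """Pearson correlation of endpoint degrees over both edge orientations."""
    deg = bf_degree(adj)
    xs, ys = [], []
    n = len(adj)
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i][j]:
                xs += [deg[i], deg[j]]
                ys += [deg[j], deg[i]]
    m = len(xs)
    if m < 4:
        return None
    mx = sum(xs) / m
    my = sum(ys) / m
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return None
    return sxy / (sxx * syy) ** 0.5


def partitions(elements):
    """All set partitions (restricted-growth enumeration)."""
    elements = list(elements)
    if not elements:
        yield []
        return
    first, rest = elements[0], elements[1:]
    for sub in partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def bf_modularity_q(adj, blocks):
    total = sum(sum(row) for row in adj) / 2
    q = 0.0
    for block in blocks:
        l_m = sum(adj[i][j] for i in block for j in block) / 2
        d_m = sum(sum(adj[i]) for i in block)
        q += l_m / total - (d_m / (2 * total)) ** 2
    return q


def bf_best_modularity(adj):
    """Exhaustive max-Q over all partitions (feasible to ~8 nodes)."""
    best = None
    for blocks in partitions(range(len(adj))):
        q = bf_modularity_q(adj, blocks)
        if best is None or q > best[0]:
            best = (q, blocks)
    return best


def bf_hierarchy_slope(ks, cs):
    """Closed-form OLS slope of log(c) on log(k)."""
    import math

    lx = [math.log(k) for k in ks]
    ly = [math.log(c) for c in cs]
    n = len(lx)
    mx, my = sum(lx) / n, sum(ly) / n
    sxx = sum((x - mx) ** 2 for x in lx)
    if sxx == 0:
        return None
    sxy = sum((x - mx) * (y - my) for x, y in zip(lx, ly))
    return sxy / sxx


def random_adjacency(rng, n, p):
    """Random symmetric 0/1 adjacency as nested lists."""
    adj = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i][j] = adj[j][i] = 1
    return adj
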
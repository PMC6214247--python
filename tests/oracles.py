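"""Independent brute-force oracles for the deterministic graph measures.

Everything here works from the raw adjacency matrix with explicit
enumeration (BFS by hand, shortest-path enumeration, triangle counting,
exhaustive partition search) and never calls the package's measure code or
networkx, so it can serve as an independent reference on small graphs.
"""

from itertools import combinations

import numpy as np


def adjacency_lists(a):
    return [set(np.nonzero(a[i])[0]) for i in range(a.shape[0])]


def bfs_distances(a, source):
    adj = adjacency_lists(a)
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def all_shortest_paths(a, s, t):
    """Enumerate every shortest s-t path (list of node tuples)."""
    dist = bfs_distances(a, s)
    if t not in dist:
        return []
    adj = adjacency_lists(a)
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for v in adj[u]:
            if dist.get(v, None) == dist[u] + 1 and dist[v] <= dist[t]:
                extend(path + [v])

    extend([s])
    return [p for p in paths if len(p) - 1 == dist[t]]


def oracle_and(a):
    n = a.shape[0]
    return sum(len(adj) for adj in adjacency_lists(a)) / n


def oracle_cpl(a):
    n = a.shape[0]
    dists = []
    for i in range(n):
        d = bfs_distances(a, i)
        for j in range(i + 1, n):
            if j in d:
                dists.append(d[j])
    return sum(dists) / len(dists)


def oracle_ae(a):
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        d = bfs_distances(a, i)
        for j in range(i + 1, n):
            if j in d and d[j] > 0:
                total += 1.0 / d[j]
    return total / (n * (n - 1) / 2)


def oracle_acc(a):
    n = a.shape[0]
    adj = adjacency_lists(a)
    total = 0.0
    for i in range(n):
        k = len(adj[i])
        if k < 2:
            continue
        t = sum(1 for u, v in combinations(sorted(adj[i]), 2) if a[u, v])
        total += t / (k * (k - 1) / 2)
    return total / n


def oracle_acce(a):
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        d = bfs_distances(a, i)
        s = sum(v for k, v in d.items() if k != i)
        r = len(d) - 1  # nodes reachable from i
        total += (r / s) if s > 0 else 0.0
    return total / n


def oracle_anbc(a):
    n = a.shape[0]
    bet = [0.0] * n
    for j, k in combinations(range(n), 2):
        paths = all_shortest_paths(a, j, k)
        if not paths:
            continue
        for i in range(n):
            if i in (j, k):
                continue
            through = sum(1 for p in paths if i in p)
            bet[i] += through / len(paths)
    return sum(bet) / n


def oracle_aebc(a):
    n = a.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if a[i, j]]
    load = {e: 0.0 for e in edges}
    for j, k in combinations(range(n), 2):
        paths = all_shortest_paths(a, j, k)
        if not paths:
            continue
        for e in edges:
            through = sum(
                1 for p in paths
                if any({p[x], p[x + 1]} == set(e) for x in range(len(p) - 1))
            )
            load[e] += through / len(paths)
    return sum(load.values()) / len(edges)


def oracle_ar(a):
    n = a.shape[0]
    dist = {}
    for i in range(n):
        d = bfs_distances(a, i)
        if len(d) < n:
            return None
        dist[i] = d
    diam = max(max(d.values()) for d in dist.values())
    if diam <= 1:
        return None
    total = 0.0
    for i in range(n):
        total += sum(diam + 1 - dist[i][j] for j in range(n) if j != i) / (diam - 1)
    return total / n


def oracle_cn_lcl(a):
    n = a.shape[0]
    adj = adjacency_lists(a)
    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            if not a[i, j]:
                continue
            cohort = adj[i] & adj[j]
            if len(cohort) > 1:
                lcl = sum(1 for u, v in combinations(sorted(cohort), 2) if a[u, v])
                out[(i, j)] = (len(cohort), lcl)
    return out


def set_partitions(items):
    """All partitions of a list into non-empty blocks."""
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def oracle_modularity_opt(a):
    """Exhaustive best modularity over all node partitions."""
    n = a.shape[0]
    m = int(a.sum() // 2)
    deg = a.sum(axis=1)
    best = -1.0
    for part in set_partitions(list(range(n))):
        q = 0.0
        for block in part:
            idx = np.array(block)
            e_uu = a[np.ix_(idx, idx)].sum() / 2.0 / m
            a_u = deg[idx].sum() / (2.0 * m)
            q += e_uu - a_u**2
        best = max(best, q)
    return best


def connected_atlas_graphs(max_n=6, min_n=2):
    """Adjacency matrices of every connected graph with min_n <= n <= max_n."""
    from networkx.generators.atlas import graph_atlas_g
    import networkx as nx

    out = []
    for g in graph_atlas_g():
        n = g.number_of_nodes()
        if n < min_n or n > max_n:
            continue
        if not nx.is_connected(g):
            continue
        out.append(nx.to_numpy_array(g))
    return out
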
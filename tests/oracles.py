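"""Brute-force oracles, independent of the package's algorithms.

Betweenness enumerates every shortest path explicitly; closeness
applies the component-corrected formula directly to BFS distances;
eigenvector centrality projects the all-ones start vector onto the
leading eigenspace from a dense eigendecomposition; the neighborhood
measures count triangles directly; the hypergeometric tail is exact
integer arithmetic.  Intended for graphs of at most ~12 nodes.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_distances(adj: dict, s):
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def _adj(g):
    return {v: sorted(g.neighbors(v)) for v in g.nodes()}


def enumerate_shortest_paths(adj: dict, s, t):
    """All shortest s-t paths as node tuples, by backward DFS on BFS levels."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(v, suffix):
        if v == s:
            paths.append((s, *suffix))
            return
        for u in adj[v]:
            if dist.get(u, math.inf) == dist[v] - 1:
                back(u, (v, *suffix))

    back(t, ())
    return paths


def bc_brute(g) -> dict:
    adj = _adj(g)
    nodes = sorted(g.nodes())
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = enumerate_shortest_paths(adj, s, t)
            if not paths:
                continue
            sigma = len(paths)
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc


def cc_brute(g) -> dict:
    adj = _adj(g)
    n = g.number_of_nodes()
    cc = {}
    for v in g.nodes():
        dist = bfs_distances(adj, v)
        r = len(dist) - 1  # others reachable from v
        total = sum(dist.values())
        if r == 0 or n == 1:
            cc[v] = 0.0
        else:
            cc[v] = (r / (n - 1)) * (r / total)
    return cc


def ec_brute(g) -> dict:
    """Limit of (A+I) power iteration from all-ones: the normalized
    projection of the start onto the leading eigenspace."""
    nodes = sorted(g.nodes())
    a = np.zeros((len(nodes), len(nodes)))
    idx = {v: i for i, v in enumerate(nodes)}
    for u, v in g.edges():
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    w, vecs = np.linalg.eigh(a)
    lead = w >= w.max() - 1e-9
    basis = vecs[:, lead]
    proj = basis @ (basis.T @ np.ones(len(nodes)))
    proj = np.abs(proj / np.linalg.norm(proj))
    return dict(zip(nodes, proj))


def nc_brute(g) -> dict:
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}
    nc = {v: 0.0 for v in g.nodes()}
    for u, v in g.edges():
        z = len(adj[u] & adj[v])
        denom = min(len(adj[u]) - 1, len(adj[v]) - 1)
        ecc = z / denom if denom > 0 else 0.0
        nc[u] += ecc
        nc[v] += ecc
    return nc


def lac_brute(g) -> dict:
    adj = {v: set(g.neighbors(v)) for v in g.nodes()}
    lac = {}
    for v in g.nodes():
        nb = adj[v]
        lac[v] = sum(len(adj[u] & nb) for u in nb) / len(nb) if nb else 0.0
    return lac


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by exact integer arithmetic."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return num / math.comb(N, n)
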
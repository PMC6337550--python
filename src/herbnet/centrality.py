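"""Six topological features for hub screening.

DC  degree centrality           — number of incident edges.
BC  betweenness centrality      — unnormalized shortest-path betweenness,
                                  each unordered pair counted once.
CC  closeness centrality        — Wasserman-Faust component-corrected
                                  closeness, (r/(n-1)) * (r/sum of
                                  distances), r = #reachable others.
EC  eigenvector centrality      — principal adjacency eigenvector,
                                  nonnegative, Euclidean norm 1, by
                                  (A+I) power iteration from all-ones.
NC  network centrality          — sum over incident edges of the edge
                                  clustering coefficient z(u,v) /
                                  min(deg u - 1, deg v - 1), z = number
                                  of triangles through the edge.
LAC local average connectivity  — mean degree of v's neighbors inside
                                  the subgraph induced on N(v).

These are the CytoNCA conventions; normalized betweenness and harmonic
closeness are deliberately *not* used so that median-threshold values
stay comparable across tools.  All computations are undirected and
unweighted.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from herbnet.errors import ConvergenceError, HerbnetError

logger = logging.getLogger(__name__)

FEATURES = ("dc", "bc", "cc", "ec", "nc", "lac")


def degree(g: nx.Graph) -> dict[str, int]:
    return {n: int(d) for n, d in g.degree()}


def betweenness(g: nx.Graph) -> dict[str, float]:
    """Unnormalized betweenness; pair (s,t) contributes sigma_st(v)/sigma_st once."""
    return {n: float(v) for n, v in nx.betweenness_centrality(g, normalized=False).items()}


def closeness(g: nx.Graph) -> dict[str, float]:
    """Component-corrected closeness; isolated nodes get 0."""
    return {n: float(v) for n, v in nx.closeness_centrality(g, wf_improved=True).items()}


def eigenvector(g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> dict[str, float]:
    """Principal eigenvector of the adjacency matrix, L2-normalized.

    Power iteration on A+I (same eigenvectors as A, but a strictly
    dominant leading eigenvalue) from the all-ones vector, stopped when
    the iterate moves less than ``tol`` in Euclidean norm.  With a
    degenerate leading eigenspace (e.g. isomorphic components) the
    deterministic limit is the normalized projection of the start vector
    onto that eigenspace; on a connected graph this is the Perron vector.
    """
    if g.number_of_edges() == 0:
        raise HerbnetError("eigenvector centrality undefined on a graph with no edges")
    nodes = sorted(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes)
    x = np.ones(len(nodes)) / np.sqrt(len(nodes))
    for it in range(1, max_iter + 1):
        y = a @ x + x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            return dict(zip(nodes, np.abs(y)))
        x = y
    raise ConvergenceError("eigenvector power iteration did not converge", iterations=max_iter)


def _common_neighbor_counts(g: nx.Graph) -> dict[frozenset, int]:
    adj = {n: set(g.neighbors(n)) for n in g}
    return {frozenset((u, v)): len(adj[u] & adj[v]) for u, v in g.edges()}


def network_centrality(g: nx.Graph) -> dict[str, float]:
    """Sum of edge clustering coefficients over each node's incident edges.

    ecc(u,v) = z(u,v) / min(deg u - 1, deg v - 1), where z counts the
    triangles containing the edge; a zero denominator (a degree-1
    endpoint, which cannot close a triangle) contributes 0.
    """
    deg = dict(g.degree())
    nc = {n: 0.0 for n in g}
    for edge, z in _common_neighbor_counts(g).items():
        u, v = tuple(edge)
        denom = min(deg[u] - 1, deg[v] - 1)
        ecc = z / denom if denom > 0 else 0.0
        nc[u] += ecc
        nc[v] += ecc
    return nc


def local_average_connectivity(g: nx.Graph) -> dict[str, float]:
    """Mean within-neighborhood degree of each node's neighbors.

    lac(v) averages, over u in N(v), the number of u's neighbors that
    are themselves in N(v) (= 2 * triangles through v / deg v).
    Isolated nodes get 0.
    """
    adj = {n: set(g.neighbors(n)) for n in g}
    lac = {}
    for v in g:
        nb = adj[v]
        if not nb:
            lac[v] = 0.0
            continue
        lac[v] = sum(len(adj[u] & nb) for u in nb) / len(nb)
    return lac


def compute_all(g: nx.Graph, ec_tol: float = 1e-10, ec_max_iter: int = 1000) -> pd.DataFrame:
    """All six features as a DataFrame indexed by node, in stable order.

    On edgeless graphs eigenvector centrality is undefined; the column
    is set to 0 and flagged in ``df.attrs['ec_defined']``.
    """
    if g.number_of_nodes() == 0:
        raise HerbnetError("cannot compute centralities on an empty graph")
    nodes = sorted(g.nodes())
    ec_defined = True
    try:
        ec = eigenvector(g, tol=ec_tol, max_iter=ec_max_iter)
    except HerbnetError:
        logger.warning("eigenvector centrality undefined (no edges); reporting 0")
        ec = {n: 0.0 for n in nodes}
        ec_defined = False
    df = pd.DataFrame(
        {
            "dc": degree(g),
            "bc": betweenness(g),
            "cc": closeness(g),
            "ec": ec,
            "nc": network_centrality(g),
            "lac": local_average_connectivity(g),
        }
    ).loc[nodes]
    df.index.name = "node"
    df.attrs["ec_defined"] = ec_defined
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node")
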
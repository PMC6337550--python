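"""Seed-expanded PPI networks and their merge into a core network.

Given a background interactome, each target list (drug side, disease
side) seeds a subnetwork: the subgraph induced on the seeds plus all
interactome nodes within a fixed graph distance of any seed.  The two
subnetworks are then merged; the intersection merge yields the core
PPI network (CPPI) on which hub screening runs.
"""

from __future__ import annotations

import logging

import networkx as nx

from herbnet.errors import ConfigError

logger = logging.getLogger(__name__)


def expand_seeds(interactome: nx.Graph, seeds, depth: int = 1) -> nx.Graph:
    """Induced subgraph on the seeds and their <=depth-hop neighborhood.

    ``depth`` 0 induces on the seeds alone; depth d adds every node within
    graph distance d of any seed, then induces.  Seeds absent from the
    interactome are logged and ignored.
    """
    if depth not in (0, 1, 2):
        raise ConfigError(f"depth must be 0, 1 or 2, got {depth!r}")
    seeds = set(seeds)
    if not seeds:
        logger.warning("expand_seeds: empty seed set, returning empty network")
        return nx.Graph()
    present = seeds & set(interactome.nodes())
    absent = len(seeds) - len(present)
    if absent:
        logger.info("expand_seeds: %d of %d seeds absent from interactome", absent, len(seeds))
    nodes = set(present)
    frontier = set(present)
    for _ in range(depth):
        frontier = {nb for v in frontier for nb in interactome.neighbors(v)} - nodes
        nodes |= frontier
    sub = interactome.subgraph(nodes).copy()
    logger.info("expand_seeds: %d seeds (depth %d) -> %d nodes, %d edges",
                len(present), depth, sub.number_of_nodes(), sub.number_of_edges())
    return sub


def merge_networks(a: nx.Graph, b: nx.Graph, mode: str = "intersection",
                   drop_isolated: bool = True) -> nx.Graph:
    """Merge two simple networks node- and edge-wise.

    ``intersection`` (the default, yielding a *core* network no larger
    than either input) keeps common nodes and common edges, then drops
    isolated nodes unless ``drop_isolated`` is disabled.  ``union``
    combines both component-wise.
    """
    if mode not in ("intersection", "union"):
        raise ConfigError(f"merge mode must be 'intersection' or 'union', got {mode!r}")
    g = nx.Graph()
    ea = {frozenset(e) for e in a.edges()}
    eb = {frozenset(e) for e in b.edges()}
    if mode == "union":
        g.add_nodes_from(set(a.nodes()) | set(b.nodes()))
        g.add_edges_from(tuple(e) for e in ea | eb)
    else:
        g.add_nodes_from(set(a.nodes()) & set(b.nodes()))
        g.add_edges_from(tuple(e) for e in ea & eb)
        if drop_isolated:
            g.remove_nodes_from([n for n in g if g.degree(n) == 0])
    logger.info("merge_networks(%s): %d/%d + %d/%d -> %d nodes, %d edges",
                mode, a.number_of_nodes(), a.number_of_edges(),
                b.number_of_nodes(), b.number_of_edges(),
                g.number_of_nodes(), g.number_of_edges())
    return g
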
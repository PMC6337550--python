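"""Hub screening on the core PPI network.

Two screening rules are supported:

* the six-feature median filter — keep nodes whose degree, betweenness,
  closeness, eigenvector, network centrality and local average
  connectivity each exceed the feature's network-wide median;
* the classic degree rule — a hub is a node whose degree exceeds twice
  the median degree.

The median filter is the default pipeline; the double-median degree
rule is available standalone or as a prefilter in front of the median
filter (both orderings are explicit, since the two rules compose either
way).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from herbnet.centrality import FEATURES
from herbnet.errors import ConfigError, HerbnetError

logger = logging.getLogger(__name__)


@dataclass
class HubCriteria:
    """Per-feature thresholds plus how to combine them.

    ``comparison`` 'strictly_greater' (default) keeps values > threshold;
    'at_least' keeps values >= threshold.  ``combination`` 'all' requires
    every feature to satisfy its threshold, 'any' requires one.  A
    positive ``degree_prefilter_multiplier`` m first drops nodes with
    degree <= m * median degree (m = 2 reproduces the classic hub rule).
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    comparison: str = "strictly_greater"
    combination: str = "all"
    degree_prefilter_multiplier: float = 0.0

    def __post_init__(self):
        if self.comparison not in ("strictly_greater", "at_least"):
            raise ConfigError(f"comparison must be strictly_greater or at_least, got {self.comparison!r}")
        if self.combination not in ("all", "any"):
            raise ConfigError(f"combination must be all or any, got {self.combination!r}")
        if self.degree_prefilter_multiplier < 0:
            raise ConfigError("degree_prefilter_multiplier must be >= 0")
        if self.combination == "all" and self.thresholds and set(self.thresholds) != set(FEATURES):
            raise ConfigError(
                f"with combination=all thresholds must cover exactly {FEATURES}, got {sorted(self.thresholds)}"
            )
        for k, v in self.thresholds.items():
            if not np.isfinite(v):
                raise ConfigError(f"threshold for {k!r} must be finite")


def median_thresholds(table: pd.DataFrame, **kwargs) -> HubCriteria:
    """Per-feature medians of a centrality table as hub criteria.

    Even-count medians are the mean of the central pair (numpy's
    convention), which is how fractional median thresholds arise on
    integer-valued features.
    """
    if table.empty:
        raise HerbnetError("cannot take medians of an empty centrality table")
    thresholds = {f: float(np.median(table[f].to_numpy())) for f in FEATURES}
    logger.info("median thresholds: %s", {k: round(v, 6) for k, v in thresholds.items()})
    return HubCriteria(thresholds=thresholds, **kwargs)


def double_median_degree_cutoff(degrees) -> float:
    """Hub cutoff for a degree multiset: twice the median degree.

    A node is a hub when its degree strictly exceeds this cutoff.
    """
    arr = np.asarray(list(degrees), dtype=float)
    if arr.size == 0:
        raise HerbnetError("cannot take the median degree of an empty sequence")
    return 2.0 * float(np.median(arr))


def double_median_degree_hubs(g: nx.Graph) -> set[str]:
    """Nodes whose degree strictly exceeds twice the median degree."""
    if g.number_of_nodes() == 0:
        raise HerbnetError("cannot screen hubs on an empty graph")
    cutoff = double_median_degree_cutoff(d for _, d in g.degree())
    hubs = {n for n, d in g.degree() if d > cutoff}
    logger.info("double-median degree rule: cutoff %g, %d hubs", cutoff, len(hubs))
    return hubs


def filter_hubs(table: pd.DataFrame, criteria: HubCriteria) -> set[str]:
    """Nodes satisfying the criteria over all (or any) features.

    When ``degree_prefilter_multiplier`` > 0, rows failing the degree
    prefilter (dc <= m * median dc, median taken over the full table)
    are removed before the per-feature comparisons.
    """
    df = table
    if criteria.degree_prefilter_multiplier > 0:
        cutoff = criteria.degree_prefilter_multiplier * float(np.median(df["dc"].to_numpy()))
        df = df[df["dc"] > cutoff]
        logger.info("degree prefilter (x%g): %d of %d nodes kept",
                    criteria.degree_prefilter_multiplier, len(df), len(table))
    if df.empty or not criteria.thresholds:
        survivors = set(df.index) if not criteria.thresholds else set()
        logger.info("filter_hubs: %d survivors", len(survivors))
        return survivors
    op = (lambda col, t: col > t) if criteria.comparison == "strictly_greater" else (lambda col, t: col >= t)
    masks = [op(df[f], t) for f, t in criteria.thresholds.items()]
    mask = np.logical_and.reduce(masks) if criteria.combination == "all" else np.logical_or.reduce(masks)
    survivors = set(df.index[mask])
    logger.info("filter_hubs (%s/%s): %d survivors of %d nodes",
                criteria.combination, criteria.comparison, len(survivors), len(table))
    return survivors


def screen(table: pd.DataFrame, mode: str = "median", comparison: str = "strictly_greater",
           g: nx.Graph | None = None) -> tuple[set[str], HubCriteria | None]:
    """One-call hub screen.

    mode 'median'        — six-feature median filter on the table;
    mode 'double-degree' — twice-median-degree rule (needs the graph);
    mode 'both'          — degree prefilter (x2) first, then median
                           thresholds computed on the prefiltered table.
    """
    if mode == "median":
        criteria = median_thresholds(table, comparison=comparison)
        return filter_hubs(table, criteria), criteria
    if mode == "double-degree":
        if g is None:
            raise ConfigError("mode=double-degree requires the network")
        return double_median_degree_hubs(g), None
    if mode == "both":
        cutoff = 2.0 * float(np.median(table["dc"].to_numpy()))
        pre = table[table["dc"] > cutoff]
        if pre.empty:
            logger.warning("degree prefilter removed every node")
            return set(), None
        criteria = median_thresholds(pre, comparison=comparison)
        return filter_hubs(pre, criteria), criteria
    raise ConfigError(f"unknown hub mode {mode!r}")
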
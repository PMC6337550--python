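"""Compound-target mapping, per-herb target sets and the bipartite network.

A :class:`TargetMap` holds deduplicated (compound, target, herb)
associations from any mix of prediction sources.  Downstream consumers
need three views of it: per-herb target sets (with their union, the
formula's predicted target space), the intersection of that union with
a disease gene list, and the compound-target bipartite graph whose
degrees identify the formula's most promiscuous compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from herbnet.adme import ActiveSet
from herbnet.errors import ParseError

logger = logging.getLogger(__name__)

_TM_COLUMNS = ["compound_id", "target_symbol", "herb", "source", "score"]

#: score thresholds for the two in-silico predictors; comparisons are strict
SVM_SCORE_MIN = 0.7
RF_SCORE_MIN = 0.8


def normalize_symbol(s: str) -> str:
    return s.strip().upper()


@dataclass
class TargetMap:
    """Deduplicated compound→target associations with herb attribution."""

    table: pd.DataFrame  # columns: compound_id, target_symbol, herb, source, score

    def __post_init__(self):
        df = self.table.copy()
        df["target_symbol"] = df["target_symbol"].map(normalize_symbol)
        bad = df["target_symbol"] == ""
        if bad.any():
            raise ParseError("target map contains empty target symbols")
        df = df.drop_duplicates(subset=["compound_id", "target_symbol", "herb"])
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def targets(self) -> set[str]:
        return set(self.table["target_symbol"])

    @property
    def compounds(self) -> set[str]:
        return set(self.table["compound_id"])

    def restrict_to(self, compound_ids: set[str]) -> "TargetMap":
        return TargetMap(self.table[self.table["compound_id"].isin(compound_ids)])

    def pairs(self) -> set[tuple[str, str]]:
        """Distinct (compound, target) edges, collapsed across herbs."""
        return set(zip(self.table["compound_id"], self.table["target_symbol"]))


def load_target_map(path, score_filter: bool = False) -> TargetMap:
    """Read compound_targets.tsv.

    With ``score_filter``, model predictions are kept only above the
    predictor-specific expectation-value cut-offs (SVM strictly > 0.7,
    random forest strictly > 0.8); unscored rows and other sources pass
    through unchanged.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "target_symbol": str, "herb": str, "source": str})
    except pd.errors.ParserError as e:  # pragma: no cover - pandas reports the line itself
        raise ParseError(f"malformed target map: {e}", path) from e
    missing = set(_TM_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"target map missing columns: {sorted(missing)}", path)
    if df.empty:
        logger.warning("load_target_map: %s is empty", path)
    if score_filter and not df.empty:
        scored = df["score"].notna()
        keep = ~scored
        keep |= scored & (df["source"] == "svm") & (df["score"] > SVM_SCORE_MIN)
        keep |= scored & (df["source"] == "rf") & (df["score"] > RF_SCORE_MIN)
        keep |= scored & ~df["source"].isin(["svm", "rf"])
        dropped = int((~keep).sum())
        if dropped:
            logger.info("load_target_map: score filter dropped %d associations", dropped)
        df = df[keep]
    return TargetMap(df)


def write_target_map(tmap: TargetMap, path) -> None:
    df = tmap.table.sort_values(["compound_id", "target_symbol", "herb"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def per_herb_targets(tmap: TargetMap, active: ActiveSet) -> tuple[dict[str, set[str]], set[str]]:
    """Per-herb target sets over the active compounds, plus their union.

    Herb attribution comes from the association rows themselves.  Targets
    contributed by several herbs appear in each herb's set; the union
    counts every distinct target once.
    """
    restricted = tmap.restrict_to(active.active_ids)
    per_herb: dict[str, set[str]] = {}
    for herb, sub in restricted.table.groupby("herb"):
        per_herb[str(herb)] = set(sub["target_symbol"])
    union = set().union(*per_herb.values()) if per_herb else set()
    shared = [t for t in union if sum(t in s for s in per_herb.values()) >= 2]
    logger.info(
        "per-herb targets: %d herbs, union %d targets, %d shared by >=2 herbs",
        len(per_herb),
        len(union),
        len(shared),
    )
    for herb in sorted(per_herb):
        logger.debug("  %s: %d targets", herb, len(per_herb[herb]))
    return per_herb, union


def intersect_disease(formula_targets: set[str], disease_genes) -> set[str]:
    """Exact intersection of the formula target union with a disease list.

    Symbols on both sides are normalized (upper-case, trimmed) first.
    """
    a = {normalize_symbol(t) for t in formula_targets}
    b = {normalize_symbol(g) for g in disease_genes}
    shared = a & b
    logger.info("disease intersection: %d formula targets x %d disease genes -> %d shared",
                len(a), len(b), len(shared))
    return shared


def build_ct_network(active: ActiveSet, tmap: TargetMap, include_isolated_compounds: bool = False) -> nx.Graph:
    """Build the compound-target bipartite graph.

    Edges are collapsed across herbs (an edge exists once however many
    herbs contribute it) with the contributing herbs kept as an edge
    attribute.  Compounds without any mapped target are excluded unless
    ``include_isolated_compounds`` is set.
    """
    restricted = tmap.restrict_to(active.active_ids)
    g = nx.Graph()
    herb_by_compound = {c.compound_id: c.herbs for c in active.active}
    for (cid, tgt), sub in restricted.table.groupby(["compound_id", "target_symbol"]):
        g.add_node(cid, bipartite=0, kind="compound", herbs=";".join(sorted(herb_by_compound.get(cid, ()))))
        g.add_node(tgt, bipartite=1, kind="target")
        g.add_edge(cid, tgt, herbs=";".join(sorted(set(sub["herb"]))))
    if include_isolated_compounds:
        for c in active.active:
            if c.compound_id not in g:
                g.add_node(c.compound_id, bipartite=0, kind="compound",
                           herbs=";".join(sorted(c.herbs)))
    n_compounds = sum(1 for _, d in g.nodes(data=True) if d.get("kind") == "compound")
    logger.info(
        "compound-target network: %d nodes (%d compounds, %d targets), %d interactions",
        g.number_of_nodes(), n_compounds, g.number_of_nodes() - n_compounds, g.number_of_edges(),
    )
    return g
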
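"""Readers and writers for the pipeline's plain-text formats.

Formats: SIF edge lists (``node  relation  node...``), GraphML (via
networkx), one-symbol-per-line gene lists, GMT gene-set collections,
and the TSV compound / compound-target tables.  All writers emit
deterministically ordered output so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from herbnet.adme import CompoundRecord
from herbnet.errors import ParseError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- networks

def read_sif(path) -> nx.Graph:
    """Read a SIF file as a simple undirected graph.

    Lines are whitespace-separated ``source relation target [target...]``;
    the relation token is preserved as an edge attribute but ignored
    semantically.  A line with a single token declares an isolated node.
    Two tokens (a source and a relation with no target) are malformed.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            if not parts:
                continue
            if len(parts) == 1:
                g.add_node(parts[0])
            elif len(parts) == 2:
                raise ParseError("SIF line has a relation but no target node", path, lineno)
            else:
                src, rel, *targets = parts
                for t in targets:
                    if t == src:
                        continue  # self-loops violate the simple-graph contract
                    g.add_edge(src, t, relation=rel)
    return g


def write_sif(g: nx.Graph, path, relation: str = "pp") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted((a, b))) for a, b in g.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for n in sorted(g.nodes()):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    if g.is_directed():
        logger.warning("read_graphml: %s is directed; converting to undirected", path)
        g = g.to_undirected()
    if g.is_multigraph():
        g = nx.Graph(g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_graphml(g: nx.Graph, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # stable node/edge order for reproducible bytes
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes(data=True)))
    h.add_edges_from(sorted((min(u, v), max(u, v), d) for u, v, d in g.edges(data=True)))
    nx.write_graphml(h, path)


# ---------------------------------------------------------------- gene lists

def read_gene_list(path, normalize: bool = True) -> list[str]:
    """Read one symbol per line; blank lines and ``#`` comments skipped."""
    out: list[str] = []
    with open(path) as fh:
        for raw in fh:
            s = raw.strip()
            if not s or s.startswith("#"):
                continue
            out.append(s.upper() if normalize else s)
    return out


def write_gene_list(symbols, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for s in sorted(set(symbols)):
            fh.write(f"{s}\n")


# ---------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file: ``term <TAB> description <TAB> gene...`` per line."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs term, description and >=1 member", path, lineno)
            term, desc, *members = parts
            members = [m.strip().upper() for m in members if m.strip()]
            if not members:
                raise ParseError("GMT line has no members", path, lineno)
            if term in terms:
                raise ParseError(f"duplicate term id {term!r}", path, lineno)
            terms[term] = (desc, frozenset(members))
    return terms


def write_gmt(terms: dict[str, tuple[str, frozenset[str]]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term in sorted(terms):
            desc, members = terms[term]
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------- compound tables

_COMPOUND_COLUMNS = ["compound_id", "name", "herbs", "ob", "dl", "caco2", "bbb", "hl", "whitelisted"]


def read_compounds(path) -> list[CompoundRecord]:
    """Read compounds.tsv; herbs are semicolon-separated, whitelisted is 0/1."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "name": str, "herbs": str})
    missing = set(_COMPOUND_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"compound table missing columns: {sorted(missing)}", path)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CompoundRecord(
                compound_id=str(row.compound_id),
                name=str(row.name),
                herbs=frozenset(h.strip() for h in str(row.herbs).split(";") if h.strip()),
                ob=row.ob,
                dl=row.dl,
                caco2=row.caco2,
                bbb=row.bbb,
                hl=row.hl,
                whitelisted=bool(int(row.whitelisted)),
            )
        )
    return records


def write_compounds(records, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "compound_id": c.compound_id,
            "name": c.name,
            "herbs": ";".join(sorted(c.herbs)),
            "ob": c.ob,
            "dl": c.dl,
            "caco2": c.caco2,
            "bbb": c.bbb,
            "hl": c.hl,
            "whitelisted": int(c.whitelisted),
        }
        for c in records
    ]
    pd.DataFrame(rows, columns=_COMPOUND_COLUMNS).to_csv(path, sep="\t", index=False)


def write_active_set(active_set, path) -> None:
    """Write the screen result with a status column (adme_passed/rescued)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for status, group in (("adme_passed", active_set.adme_passed), ("rescued", active_set.rescued)):
        for c in group:
            rows.append(
                {
                    "compound_id": c.compound_id,
                    "name": c.name,
                    "herbs": ";".join(sorted(c.herbs)),
                    "ob": c.ob,
                    "dl": c.dl,
                    "caco2": c.caco2,
                    "bbb": c.bbb,
                    "hl": c.hl,
                    "status": status,
                }
            )
    cols = ["compound_id", "name", "herbs", "ob", "dl", "caco2", "bbb", "hl", "status"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
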
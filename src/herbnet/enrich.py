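"""Hypergeometric term enrichment with kappa-statistic term grouping.

Candidate genes are tested against each annotation term with a
right-tailed hypergeometric test (enrichment only), multiplicity-
corrected, and the significant terms are clustered into functional
groups by single linkage over pairwise Cohen's kappa of their gene
memberships — the grouping behaviour popularized by ClueGO.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from herbnet.errors import HerbnetError, ValidationError

logger = logging.getLogger(__name__)

CORRECTIONS = {
    "benjamini_hochberg": "fdr_bh",
    "bonferroni_step_down": "holm",
}


@dataclass
class GeneSetCollection:
    """Annotation terms (id -> description, member set) over a gene universe.

    When no universe is given it defaults to the union of all term
    members.  Members must lie inside the universe.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.universe:
            self.universe = frozenset().union(*(m for _, m in self.terms.values())) if self.terms else frozenset()
        for tid, (_, members) in self.terms.items():
            if not members <= self.universe:
                raise ValidationError(f"term {tid!r} has members outside the universe")


@dataclass
class EnrichmentResult:
    term_id: str
    description: str
    k: int  # candidates in term
    K: int  # term size
    n: int  # candidates in universe
    N: int  # universe size
    p: float
    p_adj: float = float("nan")
    significant: bool = False


@dataclass
class TermGroup:
    member_term_ids: list[str]
    representative: str  # lowest-p member
    kappa_matrix: dict[tuple[str, str], float] = field(default_factory=dict)


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Right-tail P[X >= k] for X ~ Hypergeometric(N, K, n), in log space.

    N genes in the universe, K in the term, n drawn (candidates); the
    tail sums pmf terms via log-binomial coefficients and a log-sum-exp
    so very small probabilities stay accurate.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValidationError(f"hypergeom_p: {name} must be a nonnegative integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValidationError(f"hypergeom_p: need K <= N and n <= N (K={K}, n={n}, N={N})")
    if k > min(K, n):
        raise ValidationError(f"hypergeom_p: k={k} exceeds min(K, n)={min(K, n)}")
    if k <= max(0, n + K - N):
        return 1.0
    log_denom = _log_comb(N, n)
    log_terms = [_log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
                 for i in range(k, min(K, n) + 1)]
    m = max(log_terms)
    return min(1.0, math.exp(m) * sum(math.exp(t - m) for t in log_terms))


def adjust_p(pvalues, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiplicity-adjusted p-values (Benjamini-Hochberg or Holm)."""
    if method not in CORRECTIONS:
        raise ValidationError(f"unknown correction {method!r}; choose from {sorted(CORRECTIONS)}")
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method=CORRECTIONS[method])[1]


def kappa(a: frozenset[str] | set[str], b: frozenset[str] | set[str], universe) -> float:
    """Cohen's kappa of two gene sets' membership over a universe.

    Agreement is scored on the 2x2 membership table over all universe
    genes.  Degenerate chance agreement (p_e = 1, both sets empty or
    both the whole universe) gives kappa 1 for identical sets, else 0.
    """
    u = set(universe)
    if not u:
        raise HerbnetError("kappa: empty universe")
    a, b = set(a) & u, set(b) & u
    nu = len(u)
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = nu - n11 - n10 - n01
    p_o = (n11 + n00) / nu
    p_e = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (nu * nu)
    if p_e == 1.0:
        return 1.0 if a == b else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def enrich(candidates, collection: GeneSetCollection, alpha: float = 0.05,
           correction: str = "benjamini_hochberg") -> list[EnrichmentResult]:
    """Per-term right-tailed hypergeometric enrichment, sorted by p.

    Candidates outside the universe are ignored (and counted in the log);
    significance is p_adj <= alpha.
    """
    cand = {c for c in candidates} & set(collection.universe)
    dropped = len(set(candidates)) - len(cand)
    if dropped:
        logger.info("enrich: %d candidates outside the universe ignored", dropped)
    if not cand:
        raise HerbnetError("enrich: no candidate genes inside the annotation universe")
    N = len(collection.universe)
    n = len(cand)
    results = []
    for tid in sorted(collection.terms):
        desc, members = collection.terms[tid]
        K = len(members)
        k = len(cand & members)
        results.append(EnrichmentResult(tid, desc, k, K, n, N, hypergeom_p(k, K, n, N)))
    padj = adjust_p([r.p for r in results], method=correction)
    for r, q in zip(results, padj):
        r.p_adj = float(q)
        r.significant = bool(q <= alpha)
    results.sort(key=lambda r: (r.p, r.term_id))
    logger.info("enrich: %d terms tested, %d significant at alpha=%g (%s)",
                len(results), sum(r.significant for r in results), alpha, correction)
    return results


def group_terms(results: list[EnrichmentResult], collection: GeneSetCollection,
                kappa_threshold: float = 0.4) -> list[TermGroup]:
    """Single-linkage kappa clustering of the significant terms.

    Terms are linked when pairwise kappa >= threshold; groups are the
    connected components, each represented by its lowest-p member.
    Returns groups ordered by their representative's p.
    """
    sig = [r for r in results if r.significant]
    if not sig:
        logger.info("group_terms: no significant terms, nothing to group")
        return []
    g = nx.Graph()
    g.add_nodes_from(r.term_id for r in sig)
    kmat: dict[tuple[str, str], float] = {}
    by_id = {r.term_id: r for r in sig}
    ids = sorted(by_id)
    for i, t1 in enumerate(ids):
        for t2 in ids[i + 1:]:
            kv = kappa(collection.terms[t1][1], collection.terms[t2][1], collection.universe)
            kmat[(t1, t2)] = kv
            if kv >= kappa_threshold:
                g.add_edge(t1, t2)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rep = min(members, key=lambda t: (by_id[t].p, t))
        sub = {pair: kv for pair, kv in kmat.items() if pair[0] in comp and pair[1] in comp}
        groups.append(TermGroup(member_term_ids=members, representative=rep, kappa_matrix=sub))
    groups.sort(key=lambda grp: (by_id[grp.representative].p, grp.representative))
    logger.info("group_terms: %d significant terms -> %d groups at kappa >= %g",
                len(sig), len(groups), kappa_threshold)
    return groups


def enrich_and_group(candidates, collection: GeneSetCollection, alpha: float = 0.05,
                     kappa_threshold: float = 0.4, correction: str = "benjamini_hochberg",
                     ) -> tuple[list[EnrichmentResult], list[TermGroup]]:
    """Enrichment followed by kappa grouping of the significant terms."""
    results = enrich(candidates, collection, alpha=alpha, correction=correction)
    groups = group_terms(results, collection, kappa_threshold=kappa_threshold)
    return results, groups
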
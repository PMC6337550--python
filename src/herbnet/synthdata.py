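"""Synthetic study inputs with planted, exactly recoverable structure.

Every pipeline input — the compound table with its five ADME
parameters, the compound-target map, the disease gene list, the
background interactome and the annotation collection — is generated
from a single seed with known ground truth:

* an exact number of compounds passes the five-parameter ADME screen
  (each failing compound violates a known parameter, cycling through
  all five so every boundary is exercised), and an exact number of
  failing compounds carries the literature-rescue flag;
* the interactome carries a planted dense module whose induced density
  is at least the configured value, over a scale-free (preferential
  attachment) or Erdos-Renyi background;
* the drug-target pool and the disease gene list each overlap the
  planted module by configured counts, and overlap each other by an
  exact count, so seed expansion and network intersection concentrate
  the core PPI network on the module;
* exactly one annotation term is enriched (by a configurable odds
  multiplier) in the planted module.

Defaults mirror the scale of a 16-herb formula study: 1005 compounds
of which 63 pass ADME and 31 are rescued, 287 distinct predicted
targets connected by 1846 compound-target associations, and 354
disease genes sharing 41 symbols with the target pool.

Gene symbols are synthetic (``G000001``...) on purpose; nothing here
imitates real identifiers or real ADME predictor distributions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from herbnet.adme import ADME_FIELDS, AdmeThresholds, CompoundRecord
from herbnet.errors import ConfigError
from herbnet import fileio
from herbnet.targets import TargetMap

import pandas as pd

logger = logging.getLogger(__name__)

# value spans used when drawing ADME parameters around their thresholds
_SPANS = {"ob": 70.0, "dl": 0.8, "caco2": 1.5, "bbb": 1.5, "hl": 20.0}
# smallest sub-threshold offset for a violating parameter
_FAIL_GAP = {"ob": 0.5, "dl": 0.005, "caco2": 0.01, "bbb": 0.01, "hl": 0.1}


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the generator; the seed fully determines every output."""

    seed: int = 0
    n_herbs: int = 16
    n_compounds: int = 1005
    pass_fraction: float = 63 / 1005
    n_whitelisted: int = 31
    n_violations: int = 1  # sub-threshold parameters per failing compound
    n_targets: int = 287
    n_ct_edges: int = 1846
    target_module_overlap: float = 0.6  # fraction of the planted module in the target pool
    interactome_nodes: int = 500
    interactome_model: str = "scale_free"  # or "erdos_renyi"
    ba_m: int = 3
    er_p: float = 0.02
    planted_module_size: int = 60
    planted_module_density: float = 0.9
    n_disease_genes: int = 354
    disease_overlap: float = 40 / 354  # fraction of disease genes inside the planted module
    disease_target_overlap: float = 41 / 354  # fraction of disease genes in the target pool
    n_terms: int = 50
    planted_term_enrichment: float = 50.0  # odds multiplier, 1 = null construction
    term_base_rate: float = 0.05

    def validate(self) -> None:
        def _count(name):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")

        for name in ("n_herbs", "n_compounds", "n_whitelisted", "n_violations", "n_targets",
                     "n_ct_edges", "interactome_nodes", "planted_module_size",
                     "n_disease_genes", "n_terms", "ba_m"):
            _count(name)
        for name in ("pass_fraction", "target_module_overlap", "disease_overlap",
                     "disease_target_overlap", "er_p", "planted_module_density",
                     "term_base_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.n_herbs < 1:
            raise ConfigError("n_herbs must be >= 1")
        if self.interactome_model not in ("scale_free", "erdos_renyi"):
            raise ConfigError(f"interactome_model must be scale_free or erdos_renyi, got {self.interactome_model!r}")
        if self.planted_module_size > self.interactome_nodes:
            raise ConfigError("planted_module_size exceeds interactome_nodes")
        if self.planted_term_enrichment < 1.0:
            raise ConfigError("planted_term_enrichment must be >= 1")
        if not (1 <= self.n_violations <= len(ADME_FIELDS)):
            raise ConfigError(f"n_violations must be in [1, {len(ADME_FIELDS)}]")
        n_pass = round(self.pass_fraction * self.n_compounds)
        if self.n_whitelisted > self.n_compounds - n_pass:
            raise ConfigError("n_whitelisted exceeds the number of ADME-failing compounds")
        n_active = n_pass + self.n_whitelisted
        if self.n_targets > 0 and n_active == 0:
            raise ConfigError("no active compounds to carry targets (pass_fraction and n_whitelisted both zero)")
        if self.n_ct_edges < self.n_targets:
            raise ConfigError("n_ct_edges must be >= n_targets so every target is used")
        if n_active and self.n_ct_edges > n_active * self.n_targets:
            raise ConfigError("n_ct_edges exceeds the active-compound x target grid")
        if self.n_targets > self.interactome_nodes:
            raise ConfigError("n_targets exceeds interactome_nodes (targets must be interactome proteins)")
        if round(self.disease_overlap * self.n_disease_genes) > self.planted_module_size:
            raise ConfigError("disease_overlap puts more disease genes in the module than its size")
        if round(self.disease_target_overlap * self.n_disease_genes) > self.n_targets:
            raise ConfigError("disease_target_overlap exceeds the target pool size")

    # counts planted by construction, exposed for truth bookkeeping
    @property
    def n_pass(self) -> int:
        return round(self.pass_fraction * self.n_compounds)

    @property
    def n_active(self) -> int:
        return self.n_pass + self.n_whitelisted


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _gene(i: int) -> str:
    return f"G{i:06d}"


def gen_compound_table(config: SynthConfig) -> list[CompoundRecord]:
    """Compound table with an exact planted ADME pass count.

    Passing compounds draw every parameter uniformly from
    [threshold, threshold + span]; failing compounds draw
    ``n_violations`` parameters below threshold (cycling so each of the
    five parameters is the sole violator for some record) and the rest
    from the passing range.  Herb membership is many-to-many (1-3 herbs
    per compound); exactly ``n_whitelisted`` failing compounds carry the
    rescue flag.
    """
    config.validate()
    rng = _rng(config, 1)
    t = AdmeThresholds().as_dict()
    herbs = [f"Herb{h + 1:02d}" for h in range(config.n_herbs)]
    n = config.n_compounds
    status = np.zeros(n, dtype=bool)
    status[rng.choice(n, size=config.n_pass, replace=False)] = True
    fail_idx = np.flatnonzero(~status)
    whitelisted = np.zeros(n, dtype=bool)
    if config.n_whitelisted:
        whitelisted[rng.choice(fail_idx, size=config.n_whitelisted, replace=False)] = True

    records = []
    fail_counter = 0
    for i in range(n):
        values = {f: t[f] + rng.uniform(0.0, _SPANS[f]) for f in ADME_FIELDS}
        if not status[i]:
            first = fail_counter % len(ADME_FIELDS)
            extra = rng.choice(
                [j for j in range(len(ADME_FIELDS)) if j != first],
                size=config.n_violations - 1, replace=False,
            )
            for j in (first, *extra):
                f = ADME_FIELDS[j]
                low = max(0.0, t[f] - _SPANS[f]) if f == "ob" else t[f] - _SPANS[f]
                values[f] = low + rng.uniform(0.0, 1.0) * (t[f] - _FAIL_GAP[f] - low)
            fail_counter += 1
        k = int(rng.integers(1, min(3, config.n_herbs) + 1))
        member_herbs = frozenset(rng.choice(herbs, size=k, replace=False))
        records.append(
            CompoundRecord(
                compound_id=f"C{i + 1:05d}",
                name=f"compound-{i + 1:05d}",
                herbs=member_herbs,
                ob=round(values["ob"], 4),
                dl=round(values["dl"], 4),
                caco2=round(values["caco2"], 4),
                bbb=round(values["bbb"], 4),
                hl=round(values["hl"], 4),
                whitelisted=bool(whitelisted[i]),
            )
        )
    logger.info("gen_compound_table: %d compounds, %d planted passes, %d whitelisted",
                n, config.n_pass, config.n_whitelisted)
    return records


def gen_interactome(config: SynthConfig) -> tuple[nx.Graph, list[str]]:
    """Background interactome plus the planted dense module's node list.

    The background is preferential-attachment (scale-free, the realistic
    default: hub screening is only informative on heavy-tailed degree
    distributions) or Erdos-Renyi.  Random edges are then added inside a
    random node subset of the configured size until its induced density
    reaches the target.
    """
    config.validate()
    rng = _rng(config, 2)
    n = config.interactome_nodes
    if config.interactome_model == "scale_free":
        m = min(config.ba_m, max(1, n - 1))
        g0 = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    else:
        g0 = nx.gnp_random_graph(n, config.er_p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g0, {i: _gene(i) for i in range(n)})

    s = config.planted_module_size
    module: list[str] = []
    if s >= 2:
        module = sorted(_gene(i) for i in rng.choice(n, size=s, replace=False))
        required = math.ceil(config.planted_module_density * s * (s - 1) / 2)
        missing = [(u, v) for i, u in enumerate(module) for v in module[i + 1:] if not g.has_edge(u, v)]
        present = s * (s - 1) // 2 - len(missing)
        if required > present:
            pick = rng.choice(len(missing), size=required - present, replace=False)
            g.add_edges_from(missing[j] for j in pick)
    elif s == 1:
        module = [_gene(int(rng.integers(n)))]
    logger.info("gen_interactome: %s, %d nodes, %d edges, module of %d at density >= %g",
                config.interactome_model, g.number_of_nodes(), g.number_of_edges(),
                s, config.planted_module_density)
    return g, module


def _target_pool(config: SynthConfig, module: list[str], rng: np.random.Generator) -> list[str]:
    """Drug-target pool: part of the planted module plus background proteins."""
    n_mod = min(round(config.target_module_overlap * len(module)), config.n_targets)
    in_module = sorted(rng.choice(module, size=n_mod, replace=False)) if n_mod else []
    others = [_gene(i) for i in range(config.interactome_nodes) if _gene(i) not in set(module)]
    n_bg = config.n_targets - n_mod
    if n_bg > len(others):
        raise ConfigError("n_targets too large for the interactome outside the module")
    background = sorted(rng.choice(others, size=n_bg, replace=False)) if n_bg else []
    return sorted(set(in_module) | set(background))


def gen_target_map(config: SynthConfig, compounds: list[CompoundRecord],
                   module: list[str]) -> TargetMap:
    """Compound-target associations with exact planted counts.

    Exactly ``n_ct_edges`` distinct (compound, target) pairs over the
    active compounds, covering all ``n_targets`` pool proteins (so the
    per-herb union recovers the pool size exactly).  Each association is
    attributed to one of its compound's herbs.
    """
    config.validate()
    rng = _rng(config, 3)
    pool = _target_pool(config, module, rng)
    active = [c for c in compounds if c.whitelisted or _passes(c)]
    if len(active) != config.n_active:
        raise ConfigError("compound table inconsistent with config active count")
    if not pool:
        return TargetMap(pd.DataFrame(columns=["compound_id", "target_symbol", "herb", "source", "score"]))

    n_a, n_t = len(active), len(pool)
    # coverage first: every pool target gets one random active compound
    pairs = {(int(rng.integers(n_a)), j) for j in range(n_t)}
    # then fill to the exact edge count with distinct uniform grid cells
    need = config.n_ct_edges - len(pairs)
    flat = rng.permutation(n_a * n_t)
    for idx in flat:
        if need <= 0:
            break
        cell = (int(idx) // n_t, int(idx) % n_t)
        if cell not in pairs:
            pairs.add(cell)
            need -= 1
    rows = []
    for ci, tj in sorted(pairs):
        c = active[ci]
        herb = str(rng.choice(sorted(c.herbs)))
        rows.append({"compound_id": c.compound_id, "target_symbol": pool[tj],
                     "herb": herb, "source": "synthetic", "score": np.nan})
    tm = TargetMap(pd.DataFrame(rows))
    logger.info("gen_target_map: %d associations over %d active compounds and %d targets",
                len(tm), n_a, n_t)
    return tm


def _passes(c: CompoundRecord) -> bool:
    t = AdmeThresholds().as_dict()
    return all(getattr(c, f) >= t[f] for f in ADME_FIELDS)


def gen_disease_genes(config: SynthConfig, module: list[str],
                      target_pool: list[str]) -> list[str]:
    """Disease gene list with exact planted overlaps.

    ``round(disease_overlap * n)`` genes come from inside the planted
    module (preferring module genes that are also drug targets, so the
    module anchors both PPI expansions) and the list shares exactly
    ``round(disease_target_overlap * n)`` symbols with the drug-target
    pool.  The remainder are fresh symbols absent from the interactome,
    as real disease lists always exceed any one interactome.
    """
    config.validate()
    rng = _rng(config, 4)
    n = config.n_disease_genes
    n_mod = round(config.disease_overlap * n)
    n_tgt = round(config.disease_target_overlap * n)
    pool = set(target_pool)
    mod_targets = sorted(set(module) & pool)
    mod_others = sorted(set(module) - pool)

    picked: list[str] = []
    take_mt = min(n_mod, n_tgt, len(mod_targets))
    picked += list(rng.choice(mod_targets, size=take_mt, replace=False)) if take_mt else []
    rem_mod = n_mod - take_mt
    if rem_mod > len(mod_others):
        raise ConfigError("disease_overlap infeasible given target_module_overlap")
    picked += list(rng.choice(mod_others, size=rem_mod, replace=False)) if rem_mod else []
    rem_tgt = n_tgt - take_mt
    bg_targets = sorted(pool - set(module))
    if rem_tgt > len(bg_targets):
        raise ConfigError("disease_target_overlap infeasible outside the module")
    picked += list(rng.choice(bg_targets, size=rem_tgt, replace=False)) if rem_tgt else []
    n_fresh = n - len(picked)
    fresh = [_gene(config.interactome_nodes + i + 1) for i in range(n_fresh)]
    genes = sorted(set(picked) | set(fresh))
    assert len(genes) == n
    logger.info("gen_disease_genes: %d genes (%d in module, %d shared with target pool)",
                n, n_mod, n_tgt)
    return genes


def gen_annotations(config: SynthConfig, interactome: nx.Graph,
                    module: list[str]) -> dict[str, tuple[str, frozenset[str]]]:
    """Annotation terms over the interactome universe, one planted.

    Background terms include each universe gene with probability
    ``term_base_rate``.  The planted term (id ``T000001``) keeps that
    rate outside the module but multiplies the membership *odds* by
    ``planted_term_enrichment`` inside it; a multiplier of 1 reproduces
    the null construction.
    """
    config.validate()
    rng = _rng(config, 5)
    universe = sorted(interactome.nodes())
    mod = set(module)
    p0 = config.term_base_rate
    odds = p0 / (1.0 - p0) if p0 < 1 else math.inf
    odds1 = odds * config.planted_term_enrichment
    p1 = odds1 / (1.0 + odds1) if math.isfinite(odds1) else 1.0

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(config.n_terms):
        tid = f"T{t + 1:06d}"
        if t == 0:
            probs = np.where([g in mod for g in universe], p1, p0)
            desc = "synthetic planted term"
        else:
            probs = np.full(len(universe), p0)
            desc = "synthetic background term"
        mask = rng.random(len(universe)) < probs
        members = [g for g, m_ in zip(universe, mask) if m_]
        if not members:  # every term must have >= 1 member
            members = [universe[int(rng.integers(len(universe)))]]
        terms[tid] = (desc, frozenset(members))
    logger.info("gen_annotations: %d terms over %d genes (planted term T000001, odds x%g)",
                config.n_terms, len(universe), config.planted_term_enrichment)
    return terms


PLANTED_TERM_ID = "T000001"


def generate_all(config: SynthConfig) -> dict:
    """Generate every input plus the ground-truth record, in memory."""
    config.validate()
    compounds = gen_compound_table(config)
    interactome, module = gen_interactome(config)
    rng_pool = _rng(config, 3)  # same stream as gen_target_map so pools agree
    target_pool = _target_pool(config, module, rng_pool)
    tmap = gen_target_map(config, compounds, module)
    disease = gen_disease_genes(config, module, target_pool)
    annotations = gen_annotations(config, interactome, module)
    truth = {
        "seed": config.seed,
        "n_compounds": config.n_compounds,
        "n_pass": config.n_pass,
        "n_whitelisted": config.n_whitelisted,
        "n_active": config.n_active,
        "n_targets": len(set(tmap.table["target_symbol"])),
        "n_ct_edges": len(tmap.pairs()),
        "disease_target_overlap_count": round(config.disease_target_overlap * config.n_disease_genes),
        "disease_module_overlap_count": round(config.disease_overlap * config.n_disease_genes),
        "planted_module": sorted(module),
        "planted_term": PLANTED_TERM_ID,
        "target_pool_size": len(target_pool),
    }
    return {
        "config": config,
        "compounds": compounds,
        "interactome": interactome,
        "module": module,
        "target_pool": target_pool,
        "target_map": tmap,
        "disease_genes": disease,
        "annotations": annotations,
        "truth": truth,
    }


def write_all(config: SynthConfig, outdir) -> dict:
    """Generate and write the complete input bundle; returns the truth dict.

    Files: compounds.tsv, compound_targets.tsv, disease_genes.txt,
    interactome.sif, annotations.gmt, truth.json.
    """
    data = generate_all(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fileio.write_compounds(data["compounds"], outdir / "compounds.tsv")
    from herbnet.targets import write_target_map
    write_target_map(data["target_map"], outdir / "compound_targets.tsv")
    with open(outdir / "disease_genes.txt", "w") as fh:
        for g in data["disease_genes"]:
            fh.write(g + "\n")
    fileio.write_sif(data["interactome"], outdir / "interactome.sif")
    fileio.write_gmt(data["annotations"], outdir / "annotations.gmt")
    truth = dict(data["truth"])
    truth["config"] = asdict(config)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("write_all: input bundle written to %s", outdir)
    return data
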
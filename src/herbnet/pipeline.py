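"""End-to-end orchestration: screen -> targets -> CT network -> PPI ->
merge -> centrality -> hubs -> enrichment, with every intermediate
artifact written and a machine-readable run report.

The report's stage counts follow the narrative order of a formula
study: compounds collected / passed / rescued / active, predicted
targets per herb and in union, disease genes and the shared targets,
the compound-target network size, both PPI networks, the core PPI
network, the six median thresholds, the candidate hubs, and the
significant enriched terms.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from herbnet import adme, centrality, enrich, fileio, hubs, ppi, targets
from herbnet.errors import ConfigError, HerbnetError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and every stage parameter of one pipeline run."""

    compounds: str
    target_map: str
    disease_genes: str
    interactome: str
    annotations: str
    outdir: str
    whitelist: str | None = None  # optional id list; falls back to the table's flag column
    seed: int = 0
    adme_thresholds: adme.AdmeThresholds = field(default_factory=adme.AdmeThresholds)
    score_filter: bool = False
    expansion_depth: int = 1
    merge_mode: str = "intersection"
    hub_mode: str = "median"
    hub_comparison: str = "strictly_greater"
    alpha: float = 0.05
    kappa_threshold: float = 0.4
    correction: str = "benjamini_hochberg"
    universe: str = "annotations"  # or "cppi"

    def validate(self) -> None:
        for name in ("compounds", "target_map", "disease_genes", "interactome", "annotations"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"input path for {name!r} does not exist: {p}")
        if self.whitelist is not None and not Path(self.whitelist).exists():
            raise ConfigError(f"whitelist path does not exist: {self.whitelist}")
        if self.universe not in ("annotations", "cppi"):
            raise ConfigError(f"universe must be 'annotations' or 'cppi', got {self.universe!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = raw.pop("adme_thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.adme_thresholds = adme.AdmeThresholds(**thr)
        return cfg

    def digest(self) -> str:
        d = asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, write artifacts under ``config.outdir``,
    and return (and write) the run report.

    A stage failure aborts with the stage name in the exception message;
    artifacts from completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("herbnet").addHandler(log_handler)

    report: dict = {"provenance": {"config_digest": config.digest(), "seed": config.seed}}
    stage = "read-compounds"
    try:
        records = fileio.read_compounds(config.compounds)
        report["compounds_collected"] = len(records)

        stage = "adme-screen"
        wl = set(fileio.read_gene_list(config.whitelist, normalize=False)) if config.whitelist else None
        active = adme.screen_compounds(records, config.adme_thresholds, whitelist=wl)
        report.update(active.counts())
        fileio.write_active_set(active, outdir / "active_compounds.tsv")

        stage = "targets"
        tmap = targets.load_target_map(config.target_map, score_filter=config.score_filter)
        per_herb, union = targets.per_herb_targets(tmap, active)
        report["targets_per_herb"] = {h: len(s) for h, s in sorted(per_herb.items())}
        report["targets_union"] = len(union)
        fileio.write_gene_list(union, outdir / "formula_targets.txt")

        stage = "disease-intersection"
        disease = fileio.read_gene_list(config.disease_genes)
        shared = targets.intersect_disease(union, disease)
        report["disease_genes"] = len(set(disease))
        report["shared_targets"] = len(shared)
        fileio.write_gene_list(shared, outdir / "shared_targets.txt")

        stage = "ct-network"
        ct = targets.build_ct_network(active, tmap)
        report["ct_network"] = {"nodes": ct.number_of_nodes(), "edges": ct.number_of_edges()}
        fileio.write_sif(ct, outdir / "ct_network.sif")
        fileio.write_graphml(ct, outdir / "ct_network.graphml")

        stage = "ppi-expansion"
        interactome = fileio.read_sif(config.interactome)
        drug_net = ppi.expand_seeds(interactome, union, depth=config.expansion_depth)
        disease_net = ppi.expand_seeds(interactome, set(disease), depth=config.expansion_depth)
        report["drug_ppi"] = {"nodes": drug_net.number_of_nodes(), "edges": drug_net.number_of_edges()}
        report["disease_ppi"] = {"nodes": disease_net.number_of_nodes(), "edges": disease_net.number_of_edges()}
        fileio.write_sif(drug_net, outdir / "drug_ppi.sif")
        fileio.write_sif(disease_net, outdir / "disease_ppi.sif")

        stage = "merge"
        cppi = ppi.merge_networks(drug_net, disease_net, mode=config.merge_mode)
        report["cppi"] = {"nodes": cppi.number_of_nodes(), "edges": cppi.number_of_edges()}
        fileio.write_sif(cppi, outdir / "cppi.sif")

        stage = "centrality"
        if cppi.number_of_nodes() == 0:
            logger.warning("CPPI network is empty; skipping hub screening and enrichment")
            report["candidates"] = 0
            report["significant_terms"] = 0
            return _finish(report, outdir)
        table = centrality.compute_all(cppi)
        centrality.write_table(table, outdir / "centrality.tsv")

        stage = "hubs"
        candidates, criteria = hubs.screen(table, mode=config.hub_mode,
                                           comparison=config.hub_comparison, g=cppi)
        report["median_thresholds"] = (
            {k: criteria.thresholds[k] for k in sorted(criteria.thresholds)} if criteria else None
        )
        report["candidates"] = len(candidates)
        fileio.write_gene_list(candidates, outdir / "candidates.txt")
        with open(outdir / "criteria.json", "w") as fh:
            json.dump(
                {"mode": config.hub_mode, "comparison": config.hub_comparison,
                 "thresholds": report["median_thresholds"]},
                fh, indent=2, sort_keys=True)
            fh.write("\n")

        stage = "enrichment"
        terms = fileio.read_gmt(config.annotations)
        universe = frozenset(cppi.nodes()) if config.universe == "cppi" else frozenset()
        collection = enrich.GeneSetCollection(
            terms={t: (d, m & universe if universe else m) for t, (d, m) in terms.items()},
            universe=universe,
        ) if universe else enrich.GeneSetCollection(terms=terms)
        results, groups = enrich.enrich_and_group(
            candidates, collection, alpha=config.alpha,
            kappa_threshold=config.kappa_threshold, correction=config.correction)
        report["terms_tested"] = len(results)
        report["significant_terms"] = sum(r.significant for r in results)
        report["term_groups"] = len(groups)
        report["top_term"] = results[0].term_id if results else None
        _write_enrichment(results, groups, outdir)
        return _finish(report, outdir)
    except HerbnetError as e:
        raise HerbnetError(f"pipeline stage {stage!r} failed: {e}") from e
    finally:
        logging.getLogger("herbnet").removeHandler(log_handler)
        log_handler.close()


def _write_enrichment(results, groups, outdir: Path) -> None:
    import pandas as pd

    group_of = {}
    for gi, grp in enumerate(groups, start=1):
        for t in grp.member_term_ids:
            group_of[t] = gi
    rows = [
        {"term": r.term_id, "description": r.description, "k": r.k, "K": r.K,
         "n": r.n, "N": r.N, "p": r.p, "p_adj": r.p_adj,
         "significant": int(r.significant), "group_id": group_of.get(r.term_id, "")}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    payload = [
        {"group_id": gi, "representative": grp.representative, "members": grp.member_term_ids}
        for gi, grp in enumerate(groups, start=1)
    ]
    with open(outdir / "groups.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _finish(report: dict, outdir: Path) -> dict:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete; report at %s", outdir / "report.json")
    return report


def run_synthetic(synth_config, outdir, **overrides) -> tuple[dict, dict]:
    """Generate a synthetic input bundle and run the pipeline on it.

    Returns (report, truth).  ``overrides`` go to :class:`PipelineConfig`.
    """
    from herbnet import synthdata

    outdir = Path(outdir)
    indir = outdir / "inputs"
    data = synthdata.write_all(synth_config, indir)
    cfg = PipelineConfig(
        compounds=str(indir / "compounds.tsv"),
        target_map=str(indir / "compound_targets.tsv"),
        disease_genes=str(indir / "disease_genes.txt"),
        interactome=str(indir / "interactome.sif"),
        annotations=str(indir / "annotations.gmt"),
        outdir=str(outdir / "run"),
        seed=synth_config.seed,
        **overrides,
    )
    report = run_pipeline(cfg)
    return report, data["truth"]
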
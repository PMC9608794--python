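"""End-to-end orchestration: expression -> DE lists -> ceRNA network -> hubs.

``run`` executes the stages in order — differential expression, background
construction, pair scoring/network assembly, centrality/hub selection,
per-hub subnetwork extraction and (when a GMT collection is supplied)
over-representation of the network's mRNAs — writing every intermediate
artifact under the output directory and returning a machine-readable
summary with the counts at each stage and the resolved configuration.

If a filtering stage empties the analysis (no DE genes, no retained edge),
the run stops gracefully: the summary records the stop point and everything
produced up to it remains on disk.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from . import preprocess, background as background_mod, cerna, topology, subnetwork, enrichment

log = logging.getLogger("cernet.pipeline")


@dataclass
class RunConfig:
    """Paths, thresholds and flags for one pipeline run."""

    expression: str
    groups: str
    biotypes: str
    lnc_mirna: str
    mirna_mrna: str
    gmt: str | None = None
    outdir: str = "cernet_run"
    fdr_max: float = 0.05
    lfc_min: float = 1.0
    pair_p_max: float = 0.01
    min_shared: int = 3
    k: int = 8
    enrich_p_max: float = 0.05
    de_use_raw_p: bool = False
    enrich_use_raw_p: bool = False
    quantile: bool = True
    log2_offset: float | None = None
    universe_policy: str = "mrna_db"
    seed: int = 0

    INPUT_KEYS = ("expression", "groups", "biotypes", "lnc_mirna", "mirna_mrna")

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        for name in ("fdr_max", "lfc_min", "pair_p_max", "enrich_p_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_shared < 0 or self.k < 1:
            raise ValueError("min_shared must be >= 0 and k >= 1")
        for key in self.INPUT_KEYS:
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"input file for {key!r} not found: {p}")
        if self.gmt is not None and not Path(self.gmt).exists():
            raise FileNotFoundError(f"GMT file not found: {self.gmt}")

    def echo(self) -> dict:
        """Config as echoed into the summary (output location excluded so
        identical analyses into different directories compare equal)."""
        d = asdict(self)
        d.pop("outdir")
        return d


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_lines(items, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for item in items:
            fh.write(f"{item}\n")


def run(cfg: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run summary."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": cfg.echo(), "stages": {}, "stopped_at": None}

    def finish(stop: str | None = None) -> dict:
        summary["stopped_at"] = stop
        _write_json(summary, outdir / "summary.json")
        if stop:
            log.warning("[pipeline] stopped early at stage %r", stop)
        return summary

    # --- differential expression -------------------------------------------
    log.info("[preprocess] reading expression and testing genes")
    em = preprocess.read_expression(cfg.expression, cfg.groups)
    biotypes = preprocess.read_biotypes(cfg.biotypes)
    de = preprocess.de_table(em, biotypes=biotypes, quantile=cfg.quantile,
                             log2_offset=cfg.log2_offset)
    preprocess.write_de_table(de, outdir / "de_table.tsv")
    flt = preprocess.filter_de(de, biotypes, fdr_max=cfg.fdr_max,
                               lfc_min=cfg.lfc_min, use_raw_p=cfg.de_use_raw_p)
    dels, degs = list(flt.dels), list(flt.degs)
    _write_lines(dels, outdir / "dels.txt")
    _write_lines(degs, outdir / "degs.txt")
    summary["stages"]["preprocess"] = {
        "n_genes_tested": int(len(de)),
        "n_dels": len(dels), "n_degs": len(degs),
        "n_up": flt.n_up, "n_down": flt.n_down,
        "dropped_missing_biotype": flt.dropped_missing,
    }
    log.info("[preprocess] %d DELs, %d DEGs", len(dels), len(degs))
    if not dels or not degs:
        return finish("preprocess")

    # --- background ---------------------------------------------------------
    log.info("[background] building the miRNA sampling frame (policy=%s)",
             cfg.universe_policy)
    lnc_map = background_mod.read_interactions(cfg.lnc_mirna, kind="lncRNA-miRNA")
    mrna_map = background_mod.read_interactions(cfg.mirna_mrna, kind="miRNA-mRNA")
    bg = background_mod.build_background(lnc_map, mrna_map, policy=cfg.universe_policy)
    stats = background_mod.background_stats(bg)
    _write_json(stats, outdir / "background_stats.json")
    summary["stages"]["background"] = stats

    # --- ceRNA network ------------------------------------------------------
    log.info("[cerna] scoring %d x %d candidate pairs", len(dels), len(degs))
    net = cerna.build_network(dels, degs, bg, p_max=cfg.pair_p_max,
                              min_shared=cfg.min_shared)
    cerna.write_edges(net, outdir / "edges.tsv")
    cerna.write_sif(net, outdir / "network.sif")
    net_summary = cerna.network_summary(net)
    _write_json(net_summary, outdir / "network.json")
    summary["stages"]["cerna"] = net_summary
    log.info("[cerna] retained %d edges (%d lncRNAs, %d mRNAs)",
             len(net.edges), len(net.lnc_nodes), len(net.mrna_nodes))
    if not net.edges:
        return finish("cerna")

    # --- topology / hubs ----------------------------------------------------
    log.info("[topology] ranking lncRNAs by degree and betweenness (k=%d)", cfg.k)
    report = topology.select_hubs(net, k=cfg.k)
    topology.write_report(report, outdir / "centrality.tsv", outdir / "hubs.txt")
    summary["stages"]["topology"] = {"k": cfg.k, "hubs": list(report.hubs)}
    log.info("[topology] hubs: %s", ", ".join(report.hubs))

    # --- subnetworks ---------------------------------------------------------
    sub_sizes = {}
    for hub in report.hubs:
        sub = subnetwork.extract_subnetwork(hub, net)
        sub_sizes[hub] = subnetwork.export_subnetwork(sub, outdir / "subnets" / hub)
    summary["stages"]["subnetwork"] = sub_sizes

    # --- enrichment ----------------------------------------------------------
    if cfg.gmt is not None:
        log.info("[enrichment] over-representation of %d network mRNAs",
                 len(net.mrna_nodes))
        sets = enrichment.read_gmt(cfg.gmt)
        result = enrichment.ora(list(net.mrna_nodes), sets,
                                p_max=cfg.enrich_p_max,
                                adjust=not cfg.enrich_use_raw_p)
        enrichment.write_ora(result, outdir / "enrichment.tsv")
        summary["stages"]["enrichment"] = {
            "n_sets_tested": int(len(result)),
            "n_significant": int(result["significant"].sum()),
        }
    return finish(None)
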
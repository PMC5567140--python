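"""End-to-end orchestration of the integrated mRNA–miRNA analysis.

``run_all`` executes: normalisation → differential expression (moderated
t for mRNAs with BH-adjusted p, plain t for miRNAs with raw p) →
pre-ranked pathway/GO enrichment of the DE genes → hit-score consensus
targets → miRNA–mRNA integration → pathway-overlap annotation →
fold-change-weighted network, writing every intermediate TSV, a
machine-readable summary and a log that captures the resolved
configuration and seed.  Pathway enrichment ranks all DE genes by signed
fold change in a single list; positively enriched sets associate with
the up-regulated stream, negatively enriched sets with the
down-regulated one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from importlib.metadata import version as _pkg_version
from mirmint.diffexpr import (
    apply_de_filter,
    moderated_t_test,
    plain_t_test,
    write_de_table,
)
from mirmint.enrichment import (
    EnrichConfig,
    PrerankedGSEA,
    write_enrich_results,
)
from mirmint.errors import ConfigError
from mirmint.expression import log2_transform, quantile_normalize, read_matrix
from mirmint.genesets import read_gmt
from mirmint.integrate import integrate_enrichment, write_integration
from mirmint.network import (
    annotate_mirnas,
    build_network,
    export_network,
    write_annotations,
)
from mirmint.targets import build_consensus, read_target_links, write_consensus

logger = logging.getLogger(__name__)

_INPUT_FIELDS = (
    "mrna_matrix", "mrna_design", "mirna_matrix", "mirna_design",
    "gene_sets_gmt", "target_links",
)


@dataclass
class RunConfig:
    """Paths and thresholds of a full pipeline run."""

    mrna_matrix: str
    mrna_design: str
    mirna_matrix: str
    mirna_design: str
    gene_sets_gmt: str
    target_links: str
    outdir: str
    already_log: bool = True
    quantile: bool = True
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    mrna_p_column: str = "adjusted"
    mirna_p_column: str = "raw"
    q_threshold: float = 0.25
    hit_threshold: int = 5
    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_set_size: int = 15
    max_set_size: int = 500
    integration_min_size: int = 3
    integration_direction: str = "mirna_ranked"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_threshold <= 1 or not 0 <= self.q_threshold <= 1:
            raise ConfigError("p/q thresholds must lie in [0, 1]")
        if self.fc_threshold <= 0:
            raise ConfigError("fc_threshold must be positive")
        if self.hit_threshold < 1:
            raise ConfigError("hit_threshold must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def preflight(self) -> None:
        missing = [
            f"{name}={getattr(self, name)}"
            for name in _INPUT_FIELDS
            if not Path(getattr(self, name)).is_file()
        ]
        if missing:
            raise ConfigError(f"missing input files: {missing}")


def run_all(cfg: RunConfig) -> dict:
    """Execute the full flow; returns the result objects and summary."""
    cfg.preflight()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("normalize")
        mrna = read_matrix(cfg.mrna_matrix, cfg.mrna_design)
        mirna = read_matrix(cfg.mirna_matrix, cfg.mirna_design)
        mrna.is_log2 = cfg.already_log
        mirna.is_log2 = cfg.already_log
        mrna = log2_transform(mrna, already_log=cfg.already_log)
        mirna = log2_transform(mirna, already_log=cfg.already_log)
        if cfg.quantile:
            mrna = quantile_normalize(mrna)
            mirna = quantile_normalize(mirna)

        stage("differential expression")
        mrna_de = apply_de_filter(
            moderated_t_test(mrna),
            fc_threshold=cfg.fc_threshold,
            p_threshold=cfg.p_threshold,
            p_column=cfg.mrna_p_column,
        )
        mirna_de = apply_de_filter(
            plain_t_test(mirna),
            fc_threshold=cfg.fc_threshold,
            p_threshold=cfg.p_threshold,
            p_column=cfg.mirna_p_column,
        )
        write_de_table(mrna_de, outdir / "mrna_de.tsv")
        write_de_table(mirna_de, outdir / "mirna_de.tsv")

        stage("pathway enrichment")
        gene_sets = read_gmt(cfg.gene_sets_gmt)
        de_genes = mrna_de[mrna_de["direction"].isin(["up", "down"])]
        if len(de_genes) < 2:
            raise ConfigError("fewer than 2 DE genes; cannot rank")
        gsea = PrerankedGSEA(
            gene_sets=gene_sets,
            weight_exponent=cfg.weight_exponent,
            n_permutations=cfg.n_permutations,
            min_size=cfg.min_set_size,
            max_size=min(cfg.max_set_size, len(de_genes) - 1),
            seed=cfg.seed,
            p_threshold=cfg.p_threshold,
            q_threshold=cfg.q_threshold,
        ).fit(de_genes["fc_signed"])
        pathway_results = gsea.results_
        write_enrich_results(
            pathway_results, outdir / "pathway_enrichment.tsv"
        )

        stage("consensus targets")
        links = read_target_links(cfg.target_links)
        consensus = build_consensus(links, hit_threshold=cfg.hit_threshold)
        write_consensus(consensus, outdir / "consensus_targets.tsv")

        stage("integration")
        ecfg = EnrichConfig(
            weight_exponent=cfg.weight_exponent,
            n_permutations=cfg.n_permutations,
            min_size=cfg.integration_min_size,
            max_size=cfg.max_set_size,
            seed=(cfg.seed + 1) % (2**31 - 1),
            p_threshold=cfg.p_threshold,
            q_threshold=cfg.q_threshold,
        )
        ir = integrate_enrichment(
            mirna_de, mrna_de, consensus, ecfg,
            direction=cfg.integration_direction,
        )
        write_integration(ir, outdir)

        stage("annotation")
        annotations = annotate_mirnas(
            ir, pathway_results, mrna_de, gene_sets,
            p_threshold=cfg.p_threshold, q_threshold=cfg.q_threshold,
        )
        write_annotations(annotations, outdir / "mirna_annotations.tsv")

        stage("network")
        net = build_network(ir, annotations, mirna_de, mrna_de)
        export_network(net, "sif", outdir / "network.sif")
        export_network(net, "graphml", outdir / "network.graphml")
        export_network(net, "edge_tsv", outdir / "network_edges.tsv")
    except Exception as exc:
        logger.error("pipeline failed: %s", exc)
        raise

    sig = pathway_results[pathway_results["significant"]]
    summary = {
        "package_version": _pkg_version("mirmint"),
        "seed": cfg.seed,
        "n_genes": int(len(mrna_de)),
        "n_mirnas": int(len(mirna_de)),
        "n_genes_up": int((mrna_de["direction"] == "up").sum()),
        "n_genes_down": int((mrna_de["direction"] == "down").sum()),
        "n_mirnas_up": int((mirna_de["direction"] == "up").sum()),
        "n_mirnas_down": int((mirna_de["direction"] == "down").sum()),
        "n_sets_tested": int(len(pathway_results)),
        "n_sets_significant": int(len(sig)),
        "n_sets_significant_up": int((sig["nes"] > 0).sum()),
        "n_sets_significant_down": int((sig["nes"] < 0).sum()),
        "n_consensus_pairs": int(len(consensus)),
        "n_consensus_kept": int(consensus["kept"].sum())
        if len(consensus) else 0,
        **ir.summary(),
        "n_annotation_records": len(annotations),
        "network_nodes": int(net.number_of_nodes()),
        "network_edges": int(net.number_of_edges()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "outdir": outdir,
        "summary": summary,
        "mrna_de": mrna_de,
        "mirna_de": mirna_de,
        "pathway_results": pathway_results,
        "consensus": consensus,
        "integration": ir,
        "annotations": annotations,
        "network": net,
    }
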
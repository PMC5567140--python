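"""Pathway annotation of enriched miRNAs and the weighted network.

A miRNA is annotated with a pathway/GO term when its enriched target
genes overlap the differentially expressed members of a significantly
enriched pathway; the overlap genes are the evidence.  The network view
is a typed directed graph — miRNA →(targets)→ gene →(member_of)→
pathway — whose edge weights are signed fold changes: a targeting edge
carries the miRNA's FC, a membership edge the gene's FC (the edge
belongs to the gene).  Exports (SIF + edge-attribute TSV, GraphML,
round-trippable edge TSV) load directly in Cytoscape.

Pathway category labels (apoptosis, proliferation, signaling, ...) come
from an editable keyword map, since any such grouping is a curation
choice rather than a computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from mirmint.genesets import GeneSetCollection
from mirmint.integrate import IntegrationResult

logger = logging.getLogger(__name__)

DEFAULT_CATEGORIES = {
    "apopto": "Apoptosis",
    "proliferation": "Proliferation",
    "signal": "Signaling",
    "chemotaxis": "Chemotaxis",
    "cancer": "Cancer",
    "motility": "Motility",
    "cholesterol": "Cholesterol",
    "sterol": "Cholesterol",
    "migration": "Migration",
    "differentiation": "Differentiation",
}


@dataclass
class AnnotationRecord:
    mirna_id: str
    pathway_name: str
    overlap_genes: list
    category: str = "Other"


def categorize(pathway_name: str, categories=None) -> str:
    """First matching keyword (case-insensitive substring) wins."""
    categories = DEFAULT_CATEGORIES if categories is None else categories
    low = pathway_name.lower()
    for kw, label in categories.items():
        if kw.lower() in low:
            return label
    return "Other"


def annotate_mirnas(
    ir: IntegrationResult,
    pathway_results: pd.DataFrame,
    mrna_de: pd.DataFrame,
    sets: GeneSetCollection,
    categories=None,
    p_threshold: float = 0.05,
    q_threshold: float = 0.25,
) -> list[AnnotationRecord]:
    """Overlap-based pathway annotation of the enriched miRNAs.

    For each (miRNA, significant pathway) pair the overlap is the
    miRNA's enriched target genes intersected with the DE genes that
    belong to the pathway; a record is emitted iff the overlap is
    non-empty.
    """
    sig = pathway_results[
        (pathway_results["p_nominal"] < p_threshold)
        & (pathway_results["fdr_q"] <= q_threshold)
    ]
    de_genes = set(mrna_de.index[mrna_de["direction"].isin(["up", "down"])])
    targets_by_mirna: dict[str, set] = {}
    for _, row in ir.associations.iterrows():
        targets_by_mirna.setdefault(row["mirna_id"], set()).add(
            row["gene_id"]
        )
    records = []
    for mirna in sorted(targets_by_mirna):
        targets = targets_by_mirna[mirna]
        for name in sig["set_name"]:
            if name not in sets:
                continue
            pathway_de = sets[name].member_set & de_genes
            overlap = sorted(targets & pathway_de)
            if overlap:
                records.append(
                    AnnotationRecord(
                        mirna_id=mirna,
                        pathway_name=name,
                        overlap_genes=overlap,
                        category=categorize(name, categories),
                    )
                )
    logger.info("annotation: %d (miRNA, pathway) records", len(records))
    return records


def build_network(
    ir: IntegrationResult,
    annotations: list[AnnotationRecord],
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
) -> nx.DiGraph:
    """Typed miRNA→gene→pathway graph weighted by signed fold changes."""
    g = nx.DiGraph()
    missing = []
    for _, row in ir.associations.iterrows():
        mirna, gene = row["mirna_id"], row["gene_id"]
        if mirna not in mirna_de.index:
            missing.append(mirna)
            continue
        if gene not in mrna_de.index:
            missing.append(gene)
            continue
        mfc = float(mirna_de.loc[mirna, "fc_signed"])
        gfc = float(mrna_de.loc[gene, "fc_signed"])
        g.add_node(mirna, kind="mirna", fc=mfc,
                   direction=str(mirna_de.loc[mirna, "direction"]))
        g.add_node(gene, kind="gene", fc=gfc,
                   direction=str(mrna_de.loc[gene, "direction"]))
        g.add_edge(mirna, gene, interaction="targets", weight=mfc)
    if missing:
        raise ValueError(
            f"features missing from DE tables: {sorted(set(missing))}"
        )
    for rec in annotations:
        g.add_node(rec.pathway_name, kind="pathway", category=rec.category)
        for gene in rec.overlap_genes:
            if gene not in g:
                # overlap genes are associated targets by construction
                continue
            gfc = float(mrna_de.loc[gene, "fc_signed"])
            g.add_edge(gene, rec.pathway_name,
                       interaction="member_of", weight=gfc)
    return g


def export_network(g: nx.DiGraph, fmt: str, path) -> list[Path]:
    """Write the network as ``sif``, ``graphml`` or ``edge_tsv``.

    SIF gets a companion ``<stem>.edge_attrs.tsv`` with the weights;
    the edge TSV embeds node attributes so it re-imports losslessly.
    Returns the written paths.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{data['interaction']}\t{v}\n")
        attr_path = path.with_suffix(".edge_attrs.tsv")
        with open(attr_path, "w") as fh:
            fh.write("source\tinteraction\ttarget\tweight\n")
            for u, v, data in g.edges(data=True):
                fh.write(
                    f"{u}\t{data['interaction']}\t{v}\t{data['weight']:.10g}\n"
                )
        return [path, attr_path]
    if fmt == "graphml":
        nx.write_graphml(g, path)
        return [path]
    if fmt == "edge_tsv":
        rows = []
        for u, v, data in g.edges(data=True):
            ud, vd = g.nodes[u], g.nodes[v]
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "interaction": data["interaction"],
                    "weight": data["weight"],
                    "source_kind": ud.get("kind"),
                    "target_kind": vd.get("kind"),
                    "source_fc": ud.get("fc", ""),
                    "target_fc": vd.get("fc", ""),
                    "source_direction": ud.get("direction", ""),
                    "target_direction": vd.get("direction", ""),
                    "target_category": vd.get("category", ""),
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "source", "target", "interaction", "weight", "source_kind",
                "target_kind", "source_fc", "target_fc", "source_direction",
                "target_direction", "target_category",
            ],
        ).to_csv(path, sep="\t", index=False, float_format="%.10g")
        return [path]
    raise ValueError(f"unknown network format {fmt!r}")


def import_edge_tsv(path) -> nx.DiGraph:
    """Rebuild a network from an ``edge_tsv`` export."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    g = nx.DiGraph()
    for _, row in df.iterrows():
        for end, kind_col, fc_col, dir_col in (
            ("source", "source_kind", "source_fc", "source_direction"),
            ("target", "target_kind", "target_fc", "target_direction"),
        ):
            node = row[end]
            attrs = {"kind": row[kind_col]}
            if pd.notna(row[fc_col]) and row[fc_col] != "":
                attrs["fc"] = float(row[fc_col])
            if pd.notna(row[dir_col]) and row[dir_col] != "":
                attrs["direction"] = row[dir_col]
            if (
                end == "target"
                and row["target_kind"] == "pathway"
                and pd.notna(row.get("target_category"))
                and row["target_category"] != ""
            ):
                attrs["category"] = row["target_category"]
            g.add_node(node, **attrs)
        g.add_edge(
            row["source"], row["target"],
            interaction=row["interaction"], weight=float(row["weight"]),
        )
    return g


def write_annotations(records: list[AnnotationRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "pathway_name": r.pathway_name,
                "category": r.category,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in records
        ],
        columns=["mirna_id", "pathway_name", "category", "overlap_genes"],
    ).to_csv(path, sep="\t", index=False)
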
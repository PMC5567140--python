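"""Coupling of differentially expressed miRNAs and mRNAs.

The two DE tables are joined through the kept consensus targets with the
pre-ranked weighted-KS statistic.  Two constructions are supported, both
first-class because the underlying flow diagram admits either reading:

* ``mirna_ranked`` (default): the ranked list is the DE miRNAs ordered
  by signed fold change; each DE mRNA contributes a set of the DE
  miRNAs that target it.  An mRNA is "enriched" when its set passes
  p < 0.05 and FDR q <= 0.25; the miRNAs associated with it are the
  set's leading edge.
* ``mrna_ranked``: the ranked list is the DE mRNAs; each DE miRNA
  contributes its target-gene set; a miRNA is enriched when its set
  passes, and its associated genes are the leading edge.

In ``mirna_ranked`` mode the up- and down-regulated mRNAs form separate
streams (separate enrichment runs over the per-up-gene and per-down-gene
set collections, hence separate permutation FDR pools) that are merged
in the result.  ``mrna_ranked`` mode ranks the full DE-gene list in one
run: a regulon concentrated in one expression direction shows up at one
end of the signed-fold-change ranking, which is exactly what the KS
running sum detects — restricting the ranked universe to a single sign
would leave the member ranks exchangeable and the statistic powerless.
No anti-correlation constraint is imposed: both sign combinations of
regulator and target are admissible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from mirmint.enrichment import EnrichConfig, RankedList, run_preranked
from mirmint.errors import ConfigError
from mirmint.genesets import GeneSetCollection
from mirmint.targets import target_sets

logger = logging.getLogger(__name__)

ASSOC_COLUMNS = [
    "mirna_id", "gene_id", "set_name", "stream", "es", "nes",
    "p_nominal", "fdr_q",
]


@dataclass
class IntegrationResult:
    """Enriched miRNA/mRNA associations with full provenance.

    ``associations`` is a long-format table (one row per miRNA–gene
    pair) tracing every association to the enriched set and stream that
    produced it; the ``enriched_*`` lists carry the ids with their fold
    changes, split by each feature's own DE direction.
    """

    direction: str
    associations: pd.DataFrame
    enriched_mirnas_up: pd.Series = field(default_factory=pd.Series)
    enriched_mirnas_down: pd.Series = field(default_factory=pd.Series)
    enriched_targets_up: pd.Series = field(default_factory=pd.Series)
    enriched_targets_down: pd.Series = field(default_factory=pd.Series)
    enrich_tables: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "direction": self.direction,
            "n_enriched_mirnas_up": int(self.enriched_mirnas_up.size),
            "n_enriched_mirnas_down": int(self.enriched_mirnas_down.size),
            "n_enriched_targets_up": int(self.enriched_targets_up.size),
            "n_enriched_targets_down": int(self.enriched_targets_down.size),
            "n_associations": int(len(self.associations)),
        }


def _de_rows(table: pd.DataFrame) -> pd.DataFrame:
    de = table[table["direction"].isin(["up", "down"])]
    return de.sort_index()  # row-order invariance


def _stream_cfg(cfg: EnrichConfig, offset: int) -> EnrichConfig:
    # distinct sub-seed per stream keeps the two runs independent
    return replace(cfg, seed=(cfg.seed * 4 + offset) % (2**31 - 1))


def integrate_enrichment(
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    consensus: pd.DataFrame,
    cfg: EnrichConfig | None = None,
    direction: str = "mirna_ranked",
) -> IntegrationResult:
    """Pre-ranked KS coupling of DE miRNAs and DE mRNAs.

    ``mirna_de`` / ``mrna_de`` are filtered DE tables (``direction``
    column set); ``consensus`` is the hit-score consensus table.  Target
    sets use min_size 3 by default — miRNA regulons are small, the usual
    pathway floor of 15 would discard nearly everything.
    """
    if direction not in ("mirna_ranked", "mrna_ranked"):
        raise ConfigError(f"unknown direction {direction!r}")
    if cfg is None:
        cfg = EnrichConfig(min_size=3)
    de_mir = _de_rows(mirna_de)
    de_gene = _de_rows(mrna_de)
    if de_mir.empty or de_gene.empty:
        raise ConfigError(
            "integration needs non-empty filtered DE tables "
            f"(miRNAs: {len(de_mir)}, genes: {len(de_gene)})"
        )
    kept = consensus[consensus["kept"]] if len(consensus) else consensus
    if kept.empty:
        logger.warning("no kept consensus links; empty integration result")
        return IntegrationResult(
            direction=direction,
            associations=pd.DataFrame(columns=ASSOC_COLUMNS),
        )

    streams = {}
    if direction == "mirna_ranked":
        rl = RankedList.from_scores(de_mir["fc_signed"])
        for offset, stream in enumerate(("up", "down")):
            genes = de_gene.index[de_gene["direction"] == stream]
            coll = target_sets(
                kept[kept["gene_id"].isin(set(genes))],
                orientation="gene_to_mirnas",
                restrict_to=de_mir.index,
            )
            streams[stream] = _run_stream(rl, coll, cfg, offset)
    else:
        rl = RankedList.from_scores(de_gene["fc_signed"])
        coll = target_sets(
            kept[kept["mirna_id"].isin(set(de_mir.index))],
            orientation="mirna_to_genes",
            restrict_to=de_gene.index,
        )
        streams["all"] = _run_stream(rl, coll, cfg, 0)

    assoc_rows = []
    enrich_tables = {}
    for stream, res in streams.items():
        if res is None or res.empty:
            enrich_tables[stream] = res
            continue
        enrich_tables[stream] = res
        sig = res[res["significant"]]
        for _, row in sig.iterrows():
            for member in row["leading_edge"]:
                if direction == "mirna_ranked":
                    mirna, gene = member, row["set_name"]
                else:
                    mirna, gene = row["set_name"], member
                assoc_rows.append(
                    {
                        "mirna_id": mirna,
                        "gene_id": gene,
                        "set_name": row["set_name"],
                        "stream": stream,
                        "es": row["es"],
                        "nes": row["nes"],
                        "p_nominal": row["p_nominal"],
                        "fdr_q": row["fdr_q"],
                    }
                )
    assoc = pd.DataFrame(assoc_rows, columns=ASSOC_COLUMNS)
    assoc = assoc.sort_values(["stream", "set_name", "mirna_id", "gene_id"])
    assoc = assoc.reset_index(drop=True)

    def fc_series(ids, table):
        ids = sorted(set(ids))
        return table.loc[ids, "fc_signed"]

    mir_dir = de_mir["direction"]
    gene_dir = de_gene["direction"]
    mirnas = assoc["mirna_id"]
    genes = assoc["gene_id"]
    result = IntegrationResult(
        direction=direction,
        associations=assoc,
        enriched_mirnas_up=fc_series(
            [m for m in mirnas if mir_dir.get(m) == "up"], de_mir
        ),
        enriched_mirnas_down=fc_series(
            [m for m in mirnas if mir_dir.get(m) == "down"], de_mir
        ),
        enriched_targets_up=fc_series(
            [g for g in genes if gene_dir.get(g) == "up"], de_gene
        ),
        enriched_targets_down=fc_series(
            [g for g in genes if gene_dir.get(g) == "down"], de_gene
        ),
        enrich_tables=enrich_tables,
    )
    logger.info("integration (%s): %s", direction, result.summary())
    return result


def _run_stream(rl, coll: GeneSetCollection, cfg: EnrichConfig, offset: int):
    if len(coll) == 0:
        return None
    # apply the configured size bounds against the ranked universe
    from mirmint.genesets import size_filter

    # a set covering the whole ranked list has an undefined miss term
    filtered = size_filter(
        coll, rl.item_ids, cfg.min_size, min(cfg.max_size, len(rl) - 1)
    )
    if len(filtered) == 0:
        return None
    return run_preranked(rl, filtered, _stream_cfg(cfg, offset))


def write_integration(result: IntegrationResult, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    assoc = result.associations.copy()
    with open(outdir / "integration_associations.tsv", "w") as fh:
        fh.write(f"# direction={result.direction}\n")
        assoc.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    rows = []
    for label, series in (
        ("mirna_up", result.enriched_mirnas_up),
        ("mirna_down", result.enriched_mirnas_down),
        ("target_up", result.enriched_targets_up),
        ("target_down", result.enriched_targets_down),
    ):
        for fid, fc in series.items():
            rows.append({"kind": label, "feature_id": fid, "fc_signed": fc})
    pd.DataFrame(rows, columns=["kind", "feature_id", "fc_signed"]).to_csv(
        outdir / "integration_summary.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
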
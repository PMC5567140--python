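"""Consensus miRNA→target mapping (the "hit score" reliability rule).

miRNA–target link predictions from several databases are collapsed per
(miRNA, gene) pair; a pair is kept when it is experimentally validated
in any source or predicted by at least ``hit_threshold`` distinct
databases (default 5).  Database names are compared case-insensitively;
miRNA/gene identifiers are opaque case-sensitive strings — no attempt is
made to reconcile mature-arm suffixes (e.g. ``-5p``), which a caller can
pre-map if needed.
"""

from __future__ import annotations

import logging

import pandas as pd

from mirmint.errors import FormatError
from mirmint.genesets import GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["mirna_id", "gene_id", "database", "validated"]


def read_target_links(path) -> pd.DataFrame:
    """Read a link TSV (mirna_id, gene_id, database, validated∈{0,1})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LINK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["validated"] = df["validated"].astype(int).astype(bool)
    _validate_links(df)
    return df


def write_target_links(links: pd.DataFrame, path) -> None:
    out = links.copy()
    out["validated"] = out["validated"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def _validate_links(links: pd.DataFrame) -> None:
    bad_rows = []
    for col in ("mirna_id", "gene_id", "database"):
        empty = links[col].isna() | (links[col].astype(str) == "")
        bad_rows.extend((links.index[empty] + 1).tolist())
    if bad_rows:
        raise FormatError(
            f"malformed link rows (empty ids): {sorted(set(bad_rows))[:20]}"
        )


def build_consensus(
    links: pd.DataFrame, hit_threshold: int = 5
) -> pd.DataFrame:
    """Collapse links per (miRNA, gene) into a consensus table.

    Output columns: mirna_id, gene_id, hit_score (count of distinct
    databases, case-insensitive), validated (any source validated), kept
    (validated OR hit_score >= hit_threshold).  Duplicate rows from the
    same database do not inflate the hit score.
    """
    if hit_threshold < 1:
        raise ValueError("hit_threshold must be >= 1")
    required = [c for c in LINK_COLUMNS if c not in links.columns]
    if required:
        raise FormatError(f"links table missing columns {required}")
    _validate_links(links)
    if links.empty:
        return pd.DataFrame(
            columns=["mirna_id", "gene_id", "hit_score", "validated", "kept"]
        )
    df = links.copy()
    df["database"] = df["database"].astype(str).str.lower()
    grouped = df.groupby(["mirna_id", "gene_id"], sort=True).agg(
        hit_score=("database", "nunique"),
        validated=("validated", "any"),
    )
    out = grouped.reset_index()
    out["kept"] = out["validated"] | (out["hit_score"] >= hit_threshold)
    logger.info(
        "consensus: %d pairs, %d kept (%d validated, threshold %d)",
        len(out), int(out["kept"].sum()), int(out["validated"].sum()),
        hit_threshold,
    )
    return out


def write_consensus(ct: pd.DataFrame, path) -> None:
    out = ct.copy()
    for col in ("validated", "kept"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_consensus(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    for col in ("validated", "kept"):
        df[col] = df[col].astype(bool)
    return df


def target_sets(
    ct: pd.DataFrame,
    orientation: str = "mirna_to_genes",
    restrict_to=None,
) -> GeneSetCollection:
    """Gene sets from kept consensus links.

    ``mirna_to_genes``: one set per miRNA, members = its target genes;
    ``gene_to_mirnas``: one set per gene, members = its targeting miRNAs.
    Members are intersected with ``restrict_to`` when given (e.g. the
    differentially expressed features); empty sets are dropped.
    """
    if orientation not in ("mirna_to_genes", "gene_to_mirnas"):
        raise ValueError(f"unknown orientation {orientation!r}")
    kept = ct[ct["kept"]]
    key, member = (
        ("mirna_id", "gene_id")
        if orientation == "mirna_to_genes"
        else ("gene_id", "mirna_id")
    )
    allow = set(restrict_to) if restrict_to is not None else None
    coll = GeneSetCollection()
    for name, grp in kept.groupby(key, sort=True):
        members = sorted(set(grp[member]))
        if allow is not None:
            members = [m for m in members if m in allow]
        if members:
            coll.add(GeneSet(name=str(name), description=orientation,
                             members=members))
    return coll
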
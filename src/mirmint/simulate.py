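"""Synthetic-data generator with known ground truth.

Emulates a small-n two-condition microarray study: log2 expression
matrices for genes and miRNAs (default three control vs. three treated
samples) with planted signed fold changes, a multi-database miRNA→target
link table with overlap noise and a validated subset, and gene-set
collections with planted enrichment among the differentially expressed
genes.  Every artifact is reproducible from a single integer seed: the
root seed spawns one fixed sub-stream per artifact, so adding a stage
never perturbs earlier draws.

Model per feature (log2 scale): baseline ~ Normal(baseline_mean,
baseline_sd) mimicking microarray intensities, plus the planted log2
fold change in the treated group, plus Normal(0, noise_sd) residuals.
Planted effect signs split 50/50 up/down; non-planted features carry an
exactly zero effect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mirmint.errors import ConfigError
from mirmint.expression import ExprMatrix, write_matrix
from mirmint.genesets import GeneSet, GeneSetCollection, write_gmt
from mirmint.targets import write_target_links

# fixed spawn keys: one RNG sub-stream per artifact
_STREAMS = {"mrna": 0, "mirna": 1, "targets": 2, "gene_sets": 3}


@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    Defaults mirror the emulated study: 3 samples per group, ~10% of
    features differentially expressed with mean |log2FC| 1.5 against a
    residual SD of 0.5, and an eight-database target compendium with
    per-database recall 0.7, a small spurious-link rate and a 10%
    experimentally validated subset.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    n_per_group: int = 3
    frac_de: float = 0.1
    effect_log2fc: float = 1.5
    noise_sd: float = 0.5
    n_sets: int = 50
    set_size_range: tuple = (15, 50)
    frac_enriched_sets: float = 0.2
    n_databases: int = 8
    db_recall: float = 0.7
    db_fpr: float = 1e-4
    frac_validated: float = 0.1
    seed: int = 0
    # secondary knobs (defaults chosen once; see docs/methods.md)
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    targets_per_mirna: int = 30
    frac_regulon_de: float = 0.8
    enriched_membership: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_per_group", "n_sets",
                     "n_databases", "targets_per_mirna"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("frac_de", "frac_enriched_sets", "db_recall", "db_fpr",
                     "frac_validated", "frac_regulon_de",
                     "enriched_membership"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.effect_log2fc < 0:
            raise ConfigError("effect_log2fc must be >= 0")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi <= self.n_genes):
            raise ConfigError(
                f"set_size_range must lie within [1, n_genes], got "
                f"{self.set_size_range}"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class GroundTruth:
    """Planted truth: per-feature signed log2FC (exactly 0 when not
    planted), enriched set names and the true miRNA→gene link table."""

    gene_log2fc: pd.Series | None = None
    mirna_log2fc: pd.Series | None = None
    enriched_set_names: list = field(default_factory=list)
    true_target_links: pd.DataFrame | None = None

    @property
    def de_gene_ids(self) -> list:
        s = self.gene_log2fc
        return [] if s is None else s.index[s != 0].tolist()

    @property
    def de_mirna_ids(self) -> list:
        s = self.mirna_log2fc
        return [] if s is None else s.index[s != 0].tolist()

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        def pick(a, b):
            return b if b is not None else a

        return GroundTruth(
            gene_log2fc=pick(self.gene_log2fc, other.gene_log2fc),
            mirna_log2fc=pick(self.mirna_log2fc, other.mirna_log2fc),
            enriched_set_names=self.enriched_set_names
            or other.enriched_set_names,
            true_target_links=pick(
                self.true_target_links, other.true_target_links
            ),
        )


def _feature_ids(kind: str, n: int) -> list:
    prefix = "GENE" if kind == "mrna" else "MIR"
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_expression(
    cfg: SimConfig, feature_kind: str = "mrna"
) -> tuple[ExprMatrix, GroundTruth]:
    """Two-group log2 expression with planted fold changes.

    Each feature's values are baseline + group·(planted log2FC) +
    Normal(0, noise_sd); the ground truth lists exactly the planted-DE
    features with their signed effects (50/50 up/down).
    """
    if feature_kind not in ("mrna", "mirna"):
        raise ConfigError(f"feature_kind must be mrna|mirna, got "
                          f"{feature_kind!r}")
    rng = cfg.rng(feature_kind)
    n_feat = cfg.n_genes if feature_kind == "mrna" else cfg.n_mirnas
    ids = _feature_ids(feature_kind, n_feat)
    n = cfg.n_per_group
    samples = [f"ctrl_{i + 1}" for i in range(n)] + [
        f"trt_{i + 1}" for i in range(n)
    ]
    design = pd.Series(["control"] * n + ["treated"] * n, index=samples)

    n_de = int(round(cfg.frac_de * n_feat))
    de_idx = rng.choice(n_feat, size=n_de, replace=False)
    effects = np.zeros(n_feat)
    if n_de:
        signs = np.ones(n_de)
        signs[rng.permutation(n_de)[: n_de // 2]] = -1.0
        magnitudes = np.abs(
            rng.normal(cfg.effect_log2fc, cfg.effect_log2fc * 0.1, n_de)
        )
        effects[de_idx] = signs * magnitudes

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_feat)
    noise = rng.normal(0.0, cfg.noise_sd, size=(n_feat, 2 * n))
    group_ind = np.array([0.0] * n + [1.0] * n)
    values = baseline[:, None] + effects[:, None] * group_ind[None, :] + noise
    m = ExprMatrix(
        values=pd.DataFrame(values, index=ids, columns=samples),
        design=design,
    )
    truth_series = pd.Series(effects, index=ids)
    truth = GroundTruth(
        **{
            ("gene_log2fc" if feature_kind == "mrna" else "mirna_log2fc"):
                truth_series
        }
    )
    return m, truth


def simulate_target_db(cfg: SimConfig, truth: GroundTruth):
    """Multi-database miRNA→target links with overlap noise.

    True links are drawn first (recorded in the returned GroundTruth):
    each miRNA gets ``targets_per_mirna`` targets; a differentially
    expressed miRNA draws a ``frac_regulon_de`` share of them from the
    planted DE genes of the opposite sign (repression structure: an
    up-regulated miRNA targets down-regulated genes and vice versa),
    falling back to all planted DE genes when the opposite-sign pool is
    empty.  Each true link then appears independently in each of
    ``n_databases`` with probability ``db_recall``; spurious links are
    sampled uniformly over non-true (miRNA, gene) pairs at rate
    ``db_fpr`` per database; a ``frac_validated`` subset of true links is
    emitted under the pseudo-source ``validated_experiment`` with the
    validated flag set.

    Returns ``(links_df, truth)`` with the true links filled in.
    """
    if truth.gene_log2fc is None or truth.mirna_log2fc is None:
        raise ConfigError(
            "simulate_target_db needs gene and mirna ground truth"
        )
    rng = cfg.rng("targets")
    genes = truth.gene_log2fc.index.to_numpy(object)
    mirnas = truth.mirna_log2fc.index.to_numpy(object)
    gene_lfc = truth.gene_log2fc
    de_genes = np.asarray(truth.de_gene_ids, dtype=object)
    genes_up = np.asarray(
        [g for g in de_genes if gene_lfc[g] > 0], dtype=object
    )
    genes_down = np.asarray(
        [g for g in de_genes if gene_lfc[g] < 0], dtype=object
    )
    de_mirnas = set(truth.de_mirna_ids)
    n_genes = genes.size

    true_pairs: list[tuple] = []
    k = min(cfg.targets_per_mirna, n_genes)
    for m in mirnas:
        if m in de_mirnas and de_genes.size:
            # repression structure: regulon drawn from the opposite sign
            pool = (
                genes_down if truth.mirna_log2fc[m] > 0 else genes_up
            )
            if pool.size == 0:
                pool = de_genes
            k_de = min(int(round(cfg.frac_regulon_de * k)), pool.size)
            chosen_de = rng.choice(pool, size=k_de, replace=False)
            rest_pool = np.setdiff1d(genes, chosen_de, assume_unique=False)
            chosen_bg = rng.choice(
                rest_pool, size=k - k_de, replace=False
            )
            chosen = np.concatenate([chosen_de, chosen_bg])
        else:
            chosen = rng.choice(genes, size=k, replace=False)
        true_pairs.extend((m, g) for g in chosen)
    true_df = pd.DataFrame(true_pairs, columns=["mirna_id", "gene_id"])

    db_names = [f"db{i + 1}" for i in range(cfg.n_databases)]
    rows = []
    n_true = len(true_pairs)
    for db in db_names:
        present = rng.random(n_true) < cfg.db_recall
        for (m, g), keep in zip(true_pairs, present):
            if keep:
                rows.append((m, g, db, 0))
    # spurious links: uniform over non-true pairs, per database
    gene_pos = {g: i for i, g in enumerate(genes)}
    mir_pos = {m: i for i, m in enumerate(mirnas)}
    true_codes = {
        mir_pos[m] * n_genes + gene_pos[g] for m, g in true_pairs
    }
    n_pairs = mirnas.size * n_genes
    for db in db_names:
        n_spurious = rng.binomial(n_pairs - len(true_codes), cfg.db_fpr)
        chosen: set[int] = set()
        while len(chosen) < n_spurious:
            draw = rng.integers(0, n_pairs, size=n_spurious - len(chosen))
            chosen.update(int(c) for c in draw if c not in true_codes)
        for code in sorted(chosen):
            rows.append(
                (mirnas[code // n_genes], genes[code % n_genes], db, 0)
            )
    # validated subset of true links (always emitted)
    n_val = int(round(cfg.frac_validated * n_true))
    if n_val:
        val_idx = rng.choice(n_true, size=n_val, replace=False)
        for i in sorted(val_idx):
            m, g = true_pairs[i]
            rows.append((m, g, "validated_experiment", 1))
    links = pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "database", "validated"]
    )
    links["validated"] = links["validated"].astype(bool)
    out_truth = truth.merged_with(GroundTruth(true_target_links=true_df))
    return links, out_truth


def simulate_gene_sets(cfg: SimConfig, truth: GroundTruth):
    """Gene-set collection with planted enrichment.

    ``frac_enriched_sets`` of the sets draw an ``enriched_membership``
    share of their members from planted-DE genes of a single sign
    (alternating up/down across enriched sets); all other members, and
    all members of background sets, are sampled uniformly.  Set sizes are
    uniform on ``set_size_range``.

    Returns ``(collection, truth)`` with the enriched set names filled.
    """
    if truth.gene_log2fc is None:
        raise ConfigError("simulate_gene_sets needs gene ground truth")
    rng = cfg.rng("gene_sets")
    genes = truth.gene_log2fc.index.to_numpy(object)
    lfc = truth.gene_log2fc.to_numpy(float)
    up = genes[lfc > 0]
    down = genes[lfc < 0]
    lo, hi = cfg.set_size_range
    n_enriched = int(round(cfg.frac_enriched_sets * cfg.n_sets))
    coll = GeneSetCollection()
    enriched_names = []
    width = len(str(cfg.n_sets))
    for i in range(cfg.n_sets):
        name = f"SET{i + 1:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            sign_pool = up if i % 2 == 0 else down
            if sign_pool.size == 0:
                sign_pool = genes
            k_de = min(
                int(round(cfg.enriched_membership * size)), sign_pool.size
            )
            chosen_de = rng.choice(sign_pool, size=k_de, replace=False)
            rest = np.setdiff1d(genes, chosen_de)
            chosen_bg = rng.choice(rest, size=size - k_de, replace=False)
            members = np.concatenate([chosen_de, chosen_bg])
            enriched_names.append(name)
            desc = "simulated"
        else:
            members = rng.choice(genes, size=size, replace=False)
            desc = "simulated"
        coll.add(
            GeneSet(name=name, description=desc,
                    members=[str(g) for g in members])
        )
    out_truth = truth.merged_with(GroundTruth())
    out_truth.enriched_set_names = enriched_names
    return coll, out_truth


def simulate_all(cfg: SimConfig):
    """Generate every artifact: returns a dict with matrices, links,
    gene sets and the combined ground truth."""
    mrna, t1 = simulate_expression(cfg, "mrna")
    mirna, t2 = simulate_expression(cfg, "mirna")
    truth = t1.merged_with(t2)
    links, truth = simulate_target_db(cfg, truth)
    sets, truth = simulate_gene_sets(cfg, truth)
    return {
        "mrna": mrna,
        "mirna": mirna,
        "links": links,
        "gene_sets": sets,
        "truth": truth,
    }


def write_truth(truth: GroundTruth, outdir) -> None:
    outdir = Path(outdir)
    if truth.gene_log2fc is not None:
        truth.gene_log2fc.rename("planted_log2fc").to_frame().rename_axis(
            "feature_id"
        ).to_csv(outdir / "truth_genes.tsv", sep="\t", float_format="%.10g")
    if truth.mirna_log2fc is not None:
        truth.mirna_log2fc.rename("planted_log2fc").to_frame().rename_axis(
            "feature_id"
        ).to_csv(outdir / "truth_mirnas.tsv", sep="\t", float_format="%.10g")
    pd.DataFrame({"set_name": truth.enriched_set_names}).to_csv(
        outdir / "truth_enriched_sets.tsv", sep="\t", index=False
    )
    if truth.true_target_links is not None:
        truth.true_target_links.to_csv(
            outdir / "truth_target_links.tsv", sep="\t", index=False
        )


def write_all(cfg: SimConfig, outdir) -> dict:
    """Simulate and write every artifact under ``outdir``; returns the
    in-memory objects as well."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_all(cfg)
    write_matrix(sim["mrna"], outdir / "mrna_matrix.tsv",
                 outdir / "mrna_design.tsv")
    write_matrix(sim["mirna"], outdir / "mirna_matrix.tsv",
                 outdir / "mirna_design.tsv")
    write_target_links(sim["links"], outdir / "target_links.tsv")
    write_gmt(sim["gene_sets"], outdir / "gene_sets.gmt")
    write_truth(sim["truth"], outdir)
    with open(outdir / "sim_config.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
    return sim
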
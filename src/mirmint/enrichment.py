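"""Pre-ranked gene-set enrichment: weighted KS statistic, NES, FDR.

Given a list of features ranked by a signed score (here: signed fold
change, descending) and a collection of gene sets, the enrichment score
(ES) of a set is the extremum of the running sum

    R(i) = P_hit(i) - P_miss(i)

where P_hit accumulates the |score|^p mass of in-set features
(normalised by the total in-set mass) and P_miss accumulates the count
of out-of-set features (normalised by N - N_H).  With weight exponent
p = 0 this reduces to the classical two-sample Kolmogorov–Smirnov
statistic on ranks; p = 1 is the conventional "weighted" statistic.

Significance comes from a permutation null: for every distinct set size,
B random same-size subsets of the ranked features yield null ES values
(tag shuffling — the only permutation scheme available for pre-ranked
input).  NES = ES divided by the mean same-sign null ES of the same
size; the nominal p is the same-sign tail proportion; the FDR q compares
the pooled same-sign null-NES tail with the observed-NES tail,
GSEA-style, clipped to [0, 1] and monotonised within each sign.  A
nominal p of zero is reported as < 1/B and stored as 1/(B+1) so
downstream -log transforms stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from mirmint.errors import ConfigError
from mirmint.genesets import GeneSetCollection, size_filter

logger = logging.getLogger(__name__)


@dataclass
class EnrichConfig:
    """Knobs of the pre-ranked enrichment.

    weight_exponent 1 is the conventional weighted statistic; 0 gives the
    unweighted (classical KS) variant.  Thresholds default to the joint
    significance rule p < 0.05 and FDR q <= 0.25.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    min_size: int = 15
    max_size: int = 500
    seed: int = 0
    p_threshold: float = 0.05
    q_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ConfigError("weight_exponent must be >= 0")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if self.min_size > self.max_size:
            raise ConfigError("min_size must be <= max_size")
        for name in ("p_threshold", "q_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")


@dataclass
class RankedList:
    """Feature ids with scores sorted in non-increasing order."""

    item_ids: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.item_ids = np.asarray(self.item_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.item_ids.size != self.scores.size:
            raise ValueError("ids and scores differ in length")
        if self.item_ids.size < 2:
            raise ValueError("ranked list needs >= 2 items")
        if len(set(self.item_ids)) != self.item_ids.size:
            raise ValueError("duplicate ids in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        """Sort a score series descending; ties break lexicographically
        on the feature id for determinism."""
        df = pd.DataFrame(
            {"id": scores.index.astype(str), "score": scores.to_numpy(float)}
        )
        df = df.sort_values(["score", "id"], ascending=[False, True],
                            kind="mergesort")
        return cls(df["id"].to_numpy(object), df["score"].to_numpy(float))

    def __len__(self) -> int:
        return int(self.item_ids.size)

    def positions(self, members) -> np.ndarray:
        """Sorted ranked positions of the members present in the list."""
        lookup = {g: i for i, g in enumerate(self.item_ids)}
        return np.sort(
            np.asarray([lookup[m] for m in members if m in lookup], dtype=int)
        )


def _weights(scores: np.ndarray, p_w: float) -> np.ndarray:
    if p_w == 0:
        return np.ones_like(scores)
    return np.abs(scores) ** p_w


def _es_from_hits(absw: np.ndarray, hit_idx: np.ndarray, n: int) -> float:
    """ES extremum from hit positions only (running sum is piecewise
    linear between hits: max candidates sit at hits, min just before)."""
    k = hit_idx.size
    w = absw[hit_idx]
    total = w.sum()
    if total <= 0:
        w = np.ones(k)
        total = float(k)
    cw = np.cumsum(w) / total
    denom = n - k
    j = np.arange(k)
    r_at_hit = cw - (hit_idx - j) / denom
    r_before = np.concatenate(([0.0], cw[:-1])) - (hit_idx - j) / denom
    mx = max(float(r_at_hit.max()), 0.0)
    mn = min(float(r_before.min()), 0.0)
    return mx if mx >= -mn else mn


def enrichment_score(rl: RankedList, gene_set, p_w: float = 1.0):
    """Weighted-KS enrichment score of one set against a ranked list.

    Returns ``(es, running_sum, leading_edge)`` where ``running_sum`` is
    the full length-N deviation profile and ``leading_edge`` lists the
    in-list set members at or before (positive ES) / at or after
    (negative ES) the extremum position.
    """
    members = getattr(gene_set, "members", gene_set)
    n = len(rl)
    hit_idx = rl.positions(members)
    if hit_idx.size == 0:
        raise ValueError("gene set has no member in the ranked list")
    if hit_idx.size >= n:
        raise ValueError("gene set covers the entire ranked list")
    hit = np.zeros(n, dtype=bool)
    hit[hit_idx] = True
    w = np.where(hit, _weights(rl.scores, p_w), 0.0)
    total = w.sum()
    if total <= 0:
        w = hit.astype(float)
        total = float(hit_idx.size)
    p_hit = np.cumsum(w) / total
    p_miss = np.cumsum(~hit) / (n - hit_idx.size)
    running = p_hit - p_miss
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if running[imax] >= -running[imin]:
        es, pos = float(running[imax]), imax
        leading = [rl.item_ids[i] for i in hit_idx if i <= pos]
    else:
        es, pos = float(running[imin]), imin
        leading = [rl.item_ids[i] for i in hit_idx if i >= pos]
    return es, running, leading


def permutation_null(rl: RankedList, sizes, cfg: EnrichConfig):
    """Null ES samples per distinct set size (seeded tag shuffling).

    For each size, ``cfg.n_permutations`` random same-size subsets of the
    ranked items are scored; the pool is shared by every set of that
    size.
    """
    rng = np.random.default_rng(cfg.seed)
    n = len(rl)
    absw = _weights(rl.scores, cfg.weight_exponent)
    null: dict[int, np.ndarray] = {}
    for size in sorted(set(int(s) for s in sizes)):
        if not 1 <= size < n:
            raise ValueError(f"null size {size} outside [1, N-1]")
        out = np.empty(cfg.n_permutations)
        for b in range(cfg.n_permutations):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            out[b] = _es_from_hits(absw, idx, n)
        null[size] = out
    return null


def _same_sign(null_es: np.ndarray, sign: int) -> np.ndarray:
    return null_es[null_es > 0] if sign > 0 else null_es[null_es < 0]


def nes_and_fdr(
    observed: pd.DataFrame, null: dict, cfg: EnrichConfig
) -> pd.DataFrame:
    """Attach NES, nominal p, FDR q and significance to observed ES rows.

    ``observed`` needs columns ``size`` and ``es``.  NES = ES / |mean
    same-sign null ES of the same size|; nominal p is the same-sign null
    tail proportion (0 → 1/(B+1)); q is the GSEA ratio of null-NES to
    observed-NES same-sign tail fractions, clipped to [0, 1] and
    monotonised within each sign.  Sets without same-sign null values get
    NES = NaN and are excluded from significance.
    """
    out = observed.copy()
    b = cfg.n_permutations
    nes = np.full(len(out), np.nan)
    p_nom = np.full(len(out), np.nan)
    norm = {}  # (size, sign) -> |mean same-sign null ES|
    for size in set(out["size"]):
        arr = null[int(size)]
        for sign in (1, -1):
            ss = _same_sign(arr, sign)
            norm[(int(size), sign)] = abs(ss.mean()) if ss.size else np.nan
    for i, (size, es) in enumerate(zip(out["size"], out["es"])):
        if es == 0:
            nes[i], p_nom[i] = 0.0, 1.0
            continue
        sign = 1 if es > 0 else -1
        ss = _same_sign(null[int(size)], sign)
        if ss.size == 0:
            continue  # NES undefined for this set
        nes[i] = es / norm[(int(size), sign)]
        tail = int((np.abs(ss) >= abs(es)).sum())
        p_nom[i] = tail / ss.size if tail else 1.0 / (b + 1)
    # pooled null NES, normalised per size and sign
    null_nes = []
    for size, arr in null.items():
        for sign in (1, -1):
            ss = _same_sign(arr, sign)
            f = norm[(int(size), sign)]
            if ss.size and np.isfinite(f) and f > 0:
                null_nes.append(ss / f)
    null_nes = np.concatenate(null_nes) if null_nes else np.array([])
    q = np.full(len(out), np.nan)
    for sign in (1, -1):
        obs_mask = (np.sign(nes) == sign) & np.isfinite(nes)
        if not obs_mask.any():
            continue
        obs_vals = nes[obs_mask]
        nn = null_nes[np.sign(null_nes) == sign]
        raw = np.empty(obs_vals.size)
        for j, v in enumerate(obs_vals):
            frac_null = (
                (np.abs(nn) >= abs(v)).mean() if nn.size else np.nan
            )
            frac_obs = (np.abs(obs_vals) >= abs(v)).mean()
            raw[j] = min(1.0, frac_null / frac_obs)
        # monotonise: each q becomes the min over all less-extreme sets,
        # so q never decreases as |NES| decreases (BH-style step-up)
        order = np.argsort(-np.abs(obs_vals), kind="mergesort")
        mono = raw[order][::-1]
        mono = np.minimum.accumulate(mono)[::-1]
        res = np.empty_like(raw)
        res[order] = mono
        q[obs_mask] = res
    out["nes"] = nes
    out["p_nominal"] = p_nom
    out["fdr_q"] = q
    out["significant"] = (
        np.isfinite(nes)
        & (out["p_nominal"] < cfg.p_threshold)
        & (out["fdr_q"] <= cfg.q_threshold)
    )
    return out


def run_preranked(
    rl: RankedList, coll: GeneSetCollection, cfg: EnrichConfig
) -> pd.DataFrame:
    """Full pre-ranked pipeline: ES per set, shared null, NES/p/q.

    The collection should already be size-filtered against the ranked
    universe; sets with no member in the list are skipped with a log
    entry.  Rows are sorted by NES descending.
    """
    items = set(rl.item_ids)
    rows = []
    for s in coll:
        inter = [m for m in s.members if m in items]
        if not inter:
            logger.info("set %s skipped: no member in ranked list", s.name)
            continue
        if len(inter) >= len(rl):
            raise ValueError(f"set {s.name!r} covers the entire ranked list")
        es, _, leading = enrichment_score(rl, inter, cfg.weight_exponent)
        rows.append(
            {
                "set_name": s.name,
                "size": len(inter),
                "es": es,
                "leading_edge": leading,
            }
        )
    if not rows:
        logger.warning("no gene set overlaps the ranked list")
        return pd.DataFrame(
            columns=[
                "set_name", "size", "es", "leading_edge", "nes",
                "p_nominal", "fdr_q", "significant",
            ]
        )
    obs = pd.DataFrame(rows)
    null = permutation_null(rl, obs["size"], cfg)
    res = nes_and_fdr(obs, null, cfg)
    res = res.sort_values(
        "nes", ascending=False, kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return res


class PrerankedGSEA(BaseEstimator):
    """Sklearn-style wrapper around the pre-ranked enrichment pipeline.

    Parameters mirror :class:`EnrichConfig`; ``gene_sets`` is a
    :class:`GeneSetCollection`.  ``fit`` accepts a ``pandas.Series`` of
    signed scores indexed by feature id (any order; sorting and the
    deterministic tie rule are applied internally) and exposes
    ``results_`` plus the ranked list actually used.
    """

    def __init__(
        self,
        gene_sets=None,
        weight_exponent: float = 1.0,
        n_permutations: int = 1000,
        min_size: int = 15,
        max_size: int = 500,
        seed: int = 0,
        p_threshold: float = 0.05,
        q_threshold: float = 0.25,
    ):
        self.gene_sets = gene_sets
        self.weight_exponent = weight_exponent
        self.n_permutations = n_permutations
        self.min_size = min_size
        self.max_size = max_size
        self.seed = seed
        self.p_threshold = p_threshold
        self.q_threshold = q_threshold

    def _config(self) -> EnrichConfig:
        return EnrichConfig(
            weight_exponent=self.weight_exponent,
            n_permutations=self.n_permutations,
            min_size=self.min_size,
            max_size=self.max_size,
            seed=self.seed,
            p_threshold=self.p_threshold,
            q_threshold=self.q_threshold,
        )

    def fit(self, X, y=None):
        if self.gene_sets is None:
            raise ConfigError("PrerankedGSEA needs a gene_sets collection")
        scores = X if isinstance(X, pd.Series) else pd.Series(dict(X))
        rl = RankedList.from_scores(scores)
        cfg = self._config()
        filtered = size_filter(
            self.gene_sets, rl.item_ids, cfg.min_size, cfg.max_size
        )
        self.ranked_list_ = rl
        self.results_ = run_preranked(rl, filtered, cfg)
        self.n_features_in_ = len(rl)
        return self


def write_enrich_results(res: pd.DataFrame, path) -> None:
    out = res.copy()
    if "leading_edge" in out:
        out["leading_edge"] = out["leading_edge"].map(
            lambda xs: ",".join(xs) if isinstance(xs, (list, tuple)) else xs
        )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
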
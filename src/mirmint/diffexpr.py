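"""Differential expression: moderated and plain two-sample t-tests.

The mRNA arm uses the empirical-Bayes moderated t-statistic: per-feature
sample variances s_g^2 (pooled across the two groups, d_g = n1+n2-2
residual df) are shrunk toward a prior (d0, s0^2) estimated by
moment-matching the marginal distribution of log s_g^2 under the
hierarchical scaled-F model — the digamma/trigamma closed forms.  The
posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t = log2FC / sqrt(s~_g^2 * (1/n1 + 1/n2)) is referred
to a t distribution on d0 + d_g degrees of freedom.  The miRNA arm uses
the ordinary pooled two-sample Student t.  Both report Benjamini–Hochberg
adjusted p-values; the fold-change/p filter assigns up/down/ns calls on
the signed linear fold-change scale (|FC| >= 1.5 means |log2FC| >=
log2 1.5).

Features are the unit of analysis throughout: collapsing multiple probes
onto one gene symbol is the caller's concern.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from mirmint.errors import DesignError
from mirmint.expression import ExprMatrix

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12  # zero-variance features are floored here and flagged

DE_COLUMNS = [
    "log2fc", "fc_signed", "t_stat", "p_raw", "p_adj", "direction",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order kept."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _signed_fc(log2fc: np.ndarray) -> np.ndarray:
    """Signed linear fold change: 2^|lfc| with the sign of lfc."""
    return np.sign(log2fc) * np.power(2.0, np.abs(log2fc))


def _group_arrays(m: ExprMatrix) -> tuple[np.ndarray, np.ndarray]:
    ctrl = m.samples_in_group("control")
    trt = m.samples_in_group("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise DesignError(
            "each group needs >= 2 samples for a variance estimate "
            f"(got control={len(ctrl)}, treated={len(trt)})"
        )
    return m.values[ctrl].to_numpy(), m.values[trt].to_numpy()


def _pooled_stats(x_ctrl, x_trt):
    """log2fc, pooled variance and residual df for every feature."""
    n1, n2 = x_ctrl.shape[1], x_trt.shape[1]
    lfc = x_trt.mean(axis=1) - x_ctrl.mean(axis=1)
    ss = x_ctrl.var(axis=1, ddof=1) * (n1 - 1) + x_trt.var(axis=1, ddof=1) * (
        n2 - 1
    )
    d_g = n1 + n2 - 2
    s2 = ss / d_g
    return lfc, s2, d_g, n1, n2


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, d_g: int) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2.

    Moment-matches the marginal distribution of z = log s_g^2 under the
    scaled-F hierarchical model:

        E z  = log s0^2 + digamma(d_g/2) - log(d_g/2)
               - digamma(d0/2) + log(d0/2)          (sign per model)
        Var z = trigamma(d_g/2) + trigamma(d0/2)

    so trigamma(d0/2) is the excess of Var(e) over trigamma(d_g/2), where
    e = z - digamma(d_g/2) + log(d_g/2).  A non-positive excess means no
    detectable feature-to-feature variance heterogeneity: d0 = inf and
    s0^2 is the plain mean of the sample variances.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > _VAR_FLOOR]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = e.mean()
    n = e.size
    evar = e.var(ddof=0) * n / (n - 1.0)
    excess = evar - special.polygamma(1, d_g / 2.0)
    if excess > 0:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_sq = np.exp(
            emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        s0_sq = s2.mean()
    return float(d0), float(s0_sq)


def _p_from_t(t: np.ndarray, df) -> np.ndarray:
    if np.isinf(df):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df)


class ModeratedTTest(BaseEstimator):
    """Empirical-Bayes moderated two-sample t-test (sklearn-style).

    Parameters
    ----------
    prior_df
        ``None`` (default) estimates d0 from the data by moment matching;
        ``0`` forces the ordinary pooled t-test; ``numpy.inf`` forces the
        fully shrunk limit where every posterior variance equals s0^2.

    Fitted attributes (one value per feature unless noted):
    ``log2fc_``, ``t_``, ``p_value_``, ``p_adjusted_``, ``d0_`` (scalar),
    ``s0_sq_`` (scalar), ``s2_`` (sample variances), ``s2_post_``,
    ``df_residual_`` (scalar), ``df_total_`` (scalar),
    ``zero_variance_`` (bool mask of floored features).
    """

    def __init__(self, prior_df=None):
        self.prior_df = prior_df

    def fit(self, X, y):
        """X: (n_samples, n_features); y: group labels, exactly 2 levels."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        levels = pd.unique(y)
        if len(levels) != 2:
            raise DesignError(f"need exactly 2 groups, got {list(levels)}")
        # first level observed = reference (control); second = treated
        x1 = X[y == levels[0]].T
        x2 = X[y == levels[1]].T
        if x1.shape[1] < 2 or x2.shape[1] < 2:
            raise DesignError("each group needs >= 2 samples")
        lfc, s2, d_g, n1, n2 = _pooled_stats(x1, x2)
        zero = s2 <= _VAR_FLOOR
        s2 = np.where(zero, _VAR_FLOOR, s2)
        if self.prior_df is None:
            d0, s0_sq = fit_f_dist(s2[~zero], d_g)
        else:
            d0 = float(self.prior_df)
            _, s0_sq = fit_f_dist(s2[~zero], d_g)
        if d0 == 0:
            s2_post = s2.copy()
        elif np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = lfc / se
        # total df capped at the pooled residual df across features, so
        # an infinite prior still yields a proper reference distribution
        df_total = min(d0 + d_g, len(lfc) * d_g)
        p = _p_from_t(t, df_total)
        self.classes_ = levels
        self.n_features_in_ = X.shape[1]
        self.log2fc_ = lfc
        self.s2_ = s2
        self.s2_post_ = s2_post
        self.t_ = t
        self.p_value_ = p
        self.p_adjusted_ = bh_adjust(p)
        self.d0_ = d0
        self.s0_sq_ = s0_sq
        self.df_residual_ = d_g
        self.df_total_ = df_total
        self.zero_variance_ = zero
        return self

    def results_frame(self, feature_ids=None) -> pd.DataFrame:
        lfc = self.log2fc_
        idx = (
            pd.Index(feature_ids)
            if feature_ids is not None
            else pd.RangeIndex(len(lfc))
        )
        return pd.DataFrame(
            {
                "log2fc": lfc,
                "fc_signed": _signed_fc(lfc),
                "t_stat": self.t_,
                "p_raw": self.p_value_,
                "p_adj": self.p_adjusted_,
                "direction": "ns",
                "zero_variance": self.zero_variance_,
            },
            index=idx,
        )


class PlainTTest(BaseEstimator):
    """Ordinary pooled-variance two-sample Student t-test per feature."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        levels = pd.unique(y)
        if len(levels) != 2:
            raise DesignError(f"need exactly 2 groups, got {list(levels)}")
        x1 = X[y == levels[0]]
        x2 = X[y == levels[1]]
        if x1.shape[0] < 2 or x2.shape[0] < 2:
            raise DesignError("each group needs >= 2 samples")
        res = stats.ttest_ind(x2, x1, axis=0, equal_var=True)
        lfc = x2.mean(axis=0) - x1.mean(axis=0)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        # zero pooled variance: identical groups -> t = 0, p = 1
        bad = ~np.isfinite(t)
        t[bad & (lfc == 0)] = 0.0
        p[bad & (lfc == 0)] = 1.0
        t[bad & (lfc != 0)] = np.sign(lfc[bad & (lfc != 0)]) * np.inf
        p[bad & (lfc != 0)] = 0.0
        self.classes_ = levels
        self.n_features_in_ = X.shape[1]
        self.log2fc_ = lfc
        self.t_ = t
        self.p_value_ = p
        self.p_adjusted_ = bh_adjust(p)
        self.df_residual_ = x1.shape[0] + x2.shape[0] - 2
        return self

    def results_frame(self, feature_ids=None) -> pd.DataFrame:
        idx = (
            pd.Index(feature_ids)
            if feature_ids is not None
            else pd.RangeIndex(len(self.log2fc_))
        )
        return pd.DataFrame(
            {
                "log2fc": self.log2fc_,
                "fc_signed": _signed_fc(self.log2fc_),
                "t_stat": self.t_,
                "p_raw": self.p_value_,
                "p_adj": self.p_adjusted_,
                "direction": "ns",
            },
            index=idx,
        )


def _fit_on_matrix(est, m: ExprMatrix):
    # sklearn orientation: samples x features, y = group labels in
    # control-first order so log2fc = treated - control
    order = m.samples_in_group("control") + m.samples_in_group("treated")
    X = m.values[order].T.to_numpy()
    y = np.asarray([m.design[s] for s in order])
    est.fit(X, y)
    return est.results_frame(m.feature_ids)


def moderated_t_test(m: ExprMatrix, prior_df=None) -> pd.DataFrame:
    """Moderated-t DE table (log2fc = treated − control) for a matrix."""
    return _fit_on_matrix(ModeratedTTest(prior_df=prior_df), m)


def plain_t_test(m: ExprMatrix) -> pd.DataFrame:
    """Plain pooled two-sample t DE table for a matrix."""
    return _fit_on_matrix(PlainTTest(), m)


def apply_de_filter(
    table: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    p_column: str = "adjusted",
) -> pd.DataFrame:
    """Assign up/down/ns calls by |signed FC| and the chosen p column.

    ``direction`` becomes ``up``/``down`` when |fc_signed| >= fc_threshold
    and the raw or BH-adjusted p-value is below p_threshold, ``ns``
    otherwise.  Returns a new table; up/down counts are logged.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be positive")
    if not 0 <= p_threshold <= 1:
        raise ValueError("p_threshold must lie in [0, 1]")
    if p_column not in ("raw", "adjusted"):
        raise ValueError("p_column must be 'raw' or 'adjusted'")
    col = "p_raw" if p_column == "raw" else "p_adj"
    out = table.copy()
    passed = (out["fc_signed"].abs() >= fc_threshold) & (
        out[col] < p_threshold
    )
    out["direction"] = np.where(
        passed & (out["fc_signed"] > 0),
        "up",
        np.where(passed & (out["fc_signed"] < 0), "down", "ns"),
    )
    n_up = int((out["direction"] == "up").sum())
    n_down = int((out["direction"] == "down").sum())
    logger.info(
        "DE filter |FC|>=%g, %s p<%g: %d up, %d down, %d ns",
        fc_threshold, p_column, p_threshold, n_up, n_down,
        len(out) - n_up - n_down,
    )
    return out


def write_de_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
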
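"""Expression matrices: containers, TSV IO, quantile normalisation, log2.

The in-memory container is :class:`ExprMatrix` — a features × samples
``pandas.DataFrame`` of log2 intensities together with a two-level design
(sample → ``control``/``treated``).  Normalisation mirrors the array
pre-processing applied to probe-set summaries: log2 scaling plus quantile
normalisation (each sample column is mapped onto the per-rank cross-sample
mean, so all columns end up with an identical multiset of values).
Background correction of raw probe intensities is out of scope; the
pipeline starts from probe-set summary values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from mirmint.errors import DesignError, FormatError

GROUPS = ("control", "treated")


@dataclass
class ExprMatrix:
    """Log2 expression values (features × samples) with a two-group design.

    Parameters
    ----------
    values
        DataFrame, index = unique feature ids, columns = unique sample ids.
    design
        Series mapping every sample id to ``"control"`` or ``"treated"``.
    is_log2
        Whether values are on the log2 scale (metadata only).
    """

    values: pd.DataFrame
    design: pd.Series
    is_log2: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        missing = [s for s in cols if s not in self.design.index]
        if missing:
            raise DesignError(f"samples absent from design: {missing}")
        bad = sorted(set(self.design.loc[list(cols)]) - set(GROUPS))
        if bad:
            raise DesignError(f"unknown group labels {bad}; expected {GROUPS}")
        self.design = self.design.loc[list(cols)]
        if self.values.isna().any().any():
            rows = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise FormatError(f"missing values in features: {rows[:10]}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.design[s] == group]

    def group_sizes(self) -> dict[str, int]:
        return {g: len(self.samples_in_group(g)) for g in GROUPS}


def read_matrix(path, design_path) -> ExprMatrix:
    """Read a TSV expression matrix and its design file.

    The matrix has a header row (first column = feature id, remaining
    columns = sample ids); the design file has two columns
    ``sample_id<TAB>group``.  Row order is preserved.  Duplicate ids,
    samples missing from the design and non-numeric cells are rejected.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected feature-id column plus samples")
    feat_col = raw.columns[0]
    feats = raw[feat_col]
    if feats.duplicated().any():
        dup_rows = {}
        for i, f in enumerate(feats):
            dup_rows.setdefault(f, []).append(i + 2)  # 1-based incl. header
        dups = {f: r for f, r in dup_rows.items() if len(r) > 1}
        raise FormatError(f"{path}: duplicated feature ids (rows): {dups}")
    values = raw.set_index(feat_col)
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at feature {values.index[r]!r}, "
            f"sample {values.columns[c]!r}: {values.iat[r, c]!r}"
        )
    design_df = pd.read_csv(
        design_path, sep="\t", dtype=str, names=["sample_id", "group"],
        header=0,
    )
    design = pd.Series(
        design_df["group"].values, index=design_df["sample_id"].values
    )
    return ExprMatrix(values=numeric.astype(float), design=design)


def write_matrix(m: ExprMatrix, path, design_path=None) -> None:
    """Write matrix (and optionally design) as TSV, round-trippable."""
    out = m.values.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if design_path is not None:
        pd.DataFrame(
            {"sample_id": m.design.index, "group": m.design.values}
        ).to_csv(design_path, sep="\t", index=False)


def _map_to_reference(v: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Assign sorted reference values by rank; ties get the mean of the
    reference values at the ranks they jointly occupy."""
    order = np.argsort(v, kind="stable")
    assigned = np.empty_like(ref)
    assigned[order] = ref
    uniq, inv = np.unique(v, return_inverse=True)
    sums = np.bincount(inv, weights=assigned, minlength=uniq.size)
    counts = np.bincount(inv, minlength=uniq.size)
    return (sums / counts)[inv]


def _quantile_normalize_values(values: pd.DataFrame) -> pd.DataFrame:
    ref = np.sort(values.to_numpy(), axis=0).mean(axis=1)
    out = np.column_stack(
        [_map_to_reference(values[c].to_numpy(), ref) for c in values.columns]
    )
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def quantile_normalize(m: ExprMatrix) -> ExprMatrix:
    """Quantile-normalise sample columns onto the per-rank mean.

    After normalisation every column holds the same multiset of values
    (the cross-sample means at each rank); within-column rank order is
    preserved.  Tied values receive the mean of the reference values at
    their occupied ranks.  A single-sample matrix is returned unchanged
    with a warning (nothing to normalise against).
    """
    if m.values.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returning input")
        return m
    out = _quantile_normalize_values(m.values)
    meta = dict(m.meta, quantile_normalized=True)
    return replace(m, values=out, meta=meta)


def log2_transform(m: ExprMatrix, already_log: bool = False) -> ExprMatrix:
    """Put the matrix on the log2 scale exactly once.

    With ``already_log=True`` the matrix is passed through unchanged
    (identity); otherwise all values must be strictly positive.
    """
    if already_log or m.is_log2:
        return replace(m, is_log2=True)
    vals = m.values.to_numpy()
    if (vals <= 0).any():
        r, c = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"log2_transform: non-positive value {vals[r, c]} at feature "
            f"{m.values.index[r]!r}, sample {m.values.columns[c]!r}"
        )
    out = pd.DataFrame(
        np.log2(vals), index=m.values.index, columns=m.values.columns
    )
    return replace(m, values=out, is_log2=True)


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style quantile normaliser.

    Follows the sklearn (samples × features) orientation.  ``fit`` stores
    the per-rank reference distribution (cross-sample means of the sorted
    feature vectors of each sample); ``transform`` maps each sample onto
    it.  With the default ``fit_transform`` on a single matrix this is the
    classical microarray quantile normalisation applied across the fitted
    samples themselves.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected 2-D array (n_samples, n_features)")
        self.n_features_in_ = X.shape[1]
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit")
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            out[i] = _map_to_reference(X[i], self.reference_)
        return out
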
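"""Matrix-level differential-abundance statistics for label-free proteomics.

The workflow mirrors the standard label-free pipeline: log2(x+1) transform,
per-condition missingness filter (a feature is excluded when more than a
quarter of its values are missing within any condition), k-nearest-neighbour
imputation of the remainder, per-feature linear fits with empirical-Bayes
variance moderation, Benjamini-Hochberg adjustment, and set-arithmetic overlap
accounting for condition-specific protein lists.

The moderated fit shrinks each feature's residual variance s2_g (d_g df)
toward a prior s0^2 (d0 df):

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

with (d0, s0^2) estimated by moment-matching the log residual variances
against the digamma/trigamma identities of the scaled-F model. The moderated
t is logFC / (s_post * sqrt(1/n_a + 1/n_b)) on d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "IntensityMatrix", "DifferentialResult", "OverlapCounts",
    "read_intensity_matrix", "write_intensity_matrix",
    "prepare_matrix", "filter_missingness", "knn_impute",
    "moderated_fit", "bh_adjust", "overlap_counts",
]


@dataclass
class IntensityMatrix:
    """Feature x sample matrix (NaN = missing) with a condition label per sample."""

    values: pd.DataFrame
    conditions: pd.Series
    log_scale: bool = False

    def __post_init__(self):
        self.conditions = pd.Series(self.conditions).reindex(self.values.columns)
        if self.conditions.isna().any():
            missing = list(self.conditions.index[self.conditions.isna()])
            raise ValueError(f"no condition label for samples {missing}")

    @property
    def features(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)


def read_intensity_matrix(path, conditions_path) -> IntensityMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    cond = pd.read_csv(conditions_path, sep="\t", index_col="sample_id")["condition"]
    return IntensityMatrix(values=values, conditions=cond)


def write_intensity_matrix(matrix: IntensityMatrix, path, conditions_path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    matrix.conditions.rename("condition").to_csv(
        conditions_path, sep="\t", index_label="sample_id")


def prepare_matrix(raw: IntensityMatrix) -> IntensityMatrix:
    """log2(x + 1) transform; missing cells stay missing."""
    vals = raw.values.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("raw intensities must be non-negative")
    out = raw.values.apply(lambda col: np.log2(col + 1.0))
    return IntensityMatrix(out, raw.conditions, log_scale=True)


def filter_missingness(matrix: IntensityMatrix,
                       max_frac: float = 0.25) -> IntensityMatrix:
    """Drop features whose missing fraction strictly exceeds ``max_frac`` in
    at least one condition. Exactly 25% missing (1 of 4) is retained."""
    missing = matrix.values.isna()
    drop = pd.Series(False, index=matrix.values.index)
    for cond in pd.unique(matrix.conditions):
        cols = matrix.conditions.index[matrix.conditions == cond]
        frac = missing[cols].mean(axis=1)
        drop |= frac > max_frac
    return IntensityMatrix(matrix.values.loc[~drop], matrix.conditions,
                           matrix.log_scale)


def knn_impute(matrix: IntensityMatrix, k: int = 5) -> IntensityMatrix:
    """Impute each missing cell from the k nearest feature neighbours.

    Neighbour distance between two features is the root-mean-square difference
    over their co-observed samples (normalising by the co-observed count keeps
    distances comparable across missingness patterns). For a missing cell
    (feature f, sample s), the imputed value is the plain mean of the values
    at s of the k nearest features that are observed at s. Observed cells are
    never modified.
    """
    X = matrix.values.to_numpy(dtype=float).copy()
    obs = ~np.isnan(X)
    if (~obs.any(axis=1)).any():
        bad = matrix.values.index[~obs.any(axis=1)][0]
        raise ValueError(f"feature {bad!r} has no observed values; filter first")
    if not (~obs).any():
        return IntensityMatrix(matrix.values.copy(), matrix.conditions,
                               matrix.log_scale)
    A = np.where(obs, X, 0.0)
    O = obs.astype(float)
    # sum over co-observed samples of (x_i - x_j)^2, via three rank-k products
    sq = A * A
    ss = sq @ O.T + O @ sq.T - 2.0 * (A @ A.T)
    counts = O @ O.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.sqrt(np.maximum(ss, 0.0) / counts)
    dist[counts == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = X.copy()
    miss_rows, miss_cols = np.nonzero(~obs)
    for f, s in zip(miss_rows, miss_cols):
        candidates = np.flatnonzero(obs[:, s] & np.isfinite(dist[f]))
        if candidates.size == 0:
            raise ValueError("no neighbour with an observed value is available")
        order = candidates[np.argsort(dist[f, candidates], kind="stable")]
        nearest = order[:k]
        out[f, s] = X[nearest, s].mean()
    values = pd.DataFrame(out, index=matrix.values.index,
                          columns=matrix.values.columns)
    return IntensityMatrix(values, matrix.conditions, matrix.log_scale)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated two-group fit
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-feature moderated statistics plus the fitted prior.

    ``table`` columns: log2fc, t, p, q, s2, s2_post, df_total.
    ``prior_df`` (d0) and ``prior_var`` (s0^2) describe the fitted prior;
    ``prior_df`` may be ``inf`` when the variances are homogeneous.
    """

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    contrast: Tuple[str, str]

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < fdr]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from residual variances."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    if len(e) < 2:
        return math.inf, math.exp(emean)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, math.exp(emean)
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s02


def moderated_fit(matrix: IntensityMatrix,
                  contrast: Tuple[str, str],
                  prior_df: Optional[float] = None) -> DifferentialResult:
    """Two-group moderated-t fit for ``contrast = (group_b, group_a)``.

    logFC is mean(group_b) - mean(group_a) per feature. ``prior_df`` overrides
    the estimated d0: 0 recovers the ordinary two-sample t, a huge value pools
    all features to the common prior variance. Missing values are not allowed
    (impute first).
    """
    b, a = contrast
    cond = matrix.conditions
    cols_a = cond.index[cond == a]
    cols_b = cond.index[cond == b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    Xa = matrix.values[cols_a].to_numpy(dtype=float)
    Xb = matrix.values[cols_b].to_numpy(dtype=float)
    if np.isnan(Xa).any() or np.isnan(Xb).any():
        raise ValueError("matrix contains missing values; impute before fitting")
    na, nb = Xa.shape[1], Xb.shape[1]
    df_resid = na + nb - 2
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    logfc = mean_b - mean_a
    rss = (((Xa - mean_a[:, None]) ** 2).sum(axis=1)
           + ((Xb - mean_b[:, None]) ** 2).sum(axis=1))
    s2 = rss / df_resid
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s02 = _fit_f_dist(s2, df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, np.nan)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isnan(t), np.nan, p)
    q = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    q[tested] = bh_adjust(p[tested])
    table = pd.DataFrame({
        "log2fc": logfc, "t": t, "p": p, "q": q,
        "s2": s2, "s2_post": s2_post,
        "df_total": np.full(len(s2), df_total),
    }, index=matrix.values.index)
    return DifferentialResult(table=table, prior_df=d0, prior_var=s02,
                              contrast=(b, a))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# list-overlap accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapCounts:
    only_a: int
    only_b: int
    shared: int

    @property
    def total_a(self) -> int:
        return self.only_a + self.shared

    @property
    def total_b(self) -> int:
        return self.only_b + self.shared


def overlap_counts(list_a, list_b) -> OverlapCounts:
    """Exact set arithmetic over two identifier lists (deduplicated)."""
    a, b = set(list_a), set(list_b)
    shared = len(a & b)
    return OverlapCounts(only_a=len(a) - shared, only_b=len(b) - shared,
                         shared=shared)
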
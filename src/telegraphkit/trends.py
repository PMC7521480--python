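"""Mean-variance and burstiness trends across experimental conditions.

For a gene measured under many conditions (doses, time points,
perturbations), each condition contributes one (mean, variance) point.
The linear trend sigma^2 = alpha mu + sigma0 is fitted by least squares
with an optional robust refinement that iteratively excludes points whose
residuals exceed 1.5 sigma of the residual distribution, optionally
preceded by a Mahalanobis-distance outlier filter on the (mean, variance)
cloud.  Moment burst statistics per condition (b_m = Fano, f_m =
mu/(b_m - 1)) yield companion trends of relative burst size and frequency
against the mean; the burst-size trend may be fitted either linearly or
as a power-like curve in semilog scale.  Slopes of two genes/datasets are
compared with an interaction-term t-test on the pooled regression.

Read-count data carries no absolute mRNA scale, so burst size and
frequency inferred from such matrices are *relative* quantities: trends
and their ordering are meaningful, absolute values are not.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .constraints import LinearTrend
from .estimators import moment_estimators

__all__ = [
    "ConditionSummary",
    "TrendTarget",
    "TrendModel",
    "BurstTrendFit",
    "MeanVarianceTrend",
    "summarize_conditions",
    "fit_mean_variance",
    "mahalanobis_filter",
    "gene_filters",
    "burstiness_trends",
    "compare_slopes",
    "size_normalize",
]


@dataclass(frozen=True)
class ConditionSummary:
    """Sample mean/variance (ddof=1) of one condition's per-cell counts."""

    condition: str
    mean: float
    variance: float
    n_cells: int


class TrendTarget(str, enum.Enum):
    VARIANCE = "variance"
    REL_BURST_SIZE = "rel_burst_size"
    REL_FREQUENCY = "rel_frequency"


class TrendModel(str, enum.Enum):
    LINEAR = "linear"
    POWER_SEMILOG = "power_semilog"


#: R^2 thresholds above which a fitted trend is called high-confidence.
R2_THRESHOLDS = {
    TrendTarget.VARIANCE: 0.75,
    TrendTarget.REL_FREQUENCY: 0.7,
    TrendTarget.REL_BURST_SIZE: 0.5,
}


@dataclass(frozen=True)
class BurstTrendFit:
    target: TrendTarget
    model: TrendModel
    coefficients: Tuple[float, float]  # (slope, intercept) on the model scale
    r2: float
    excluded: Tuple[int, ...]
    high_confidence: bool


def summarize_conditions(data) -> List[ConditionSummary]:
    """Per-condition sample mean and unbiased variance.

    ``data`` is a mapping {condition label -> count vector} or a long
    DataFrame with columns ``condition`` and ``count``.  Conditions with
    fewer than 2 cells are dropped with a warning.
    """
    if isinstance(data, pd.DataFrame):
        groups = {str(k): g["count"].to_numpy() for k, g in
                  data.groupby("condition", sort=False)}
    elif isinstance(data, Mapping):
        groups = {str(k): np.asarray(v) for k, v in data.items()}
    else:
        raise TypeError("expected a mapping or a (condition, count) DataFrame")
    if len(groups) < 2:
        raise ValueError("need at least 2 conditions")
    out = []
    for label, counts in groups.items():
        counts = np.asarray(counts, dtype=float)
        if counts.size < 2:
            warnings.warn(f"condition {label!r} has <2 cells, dropped")
            continue
        out.append(ConditionSummary(label, float(counts.mean()),
                                    float(counts.var(ddof=1)), counts.size))
    return out


def mahalanobis_filter(points, threshold: float = 0.05):
    """Remove (mean, variance) points far from the cloud in Mahalanobis metric.

    A point is an outlier when its squared Mahalanobis distance to the
    sample mean/covariance exceeds the chi-squared(2) quantile at
    ``1 - threshold``.  Returns ``(kept_points, outlier_indices)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if abs(np.linalg.det(cov)) < 1e-300:
        raise ValueError("singular covariance; cannot compute distances")
    inv = np.linalg.inv(cov)
    d2 = np.einsum("ij,jk,ik->i", pts - center, inv, pts - center)
    cut = stats.chi2.ppf(1.0 - threshold, df=2)
    outliers = np.nonzero(d2 > cut)[0]
    kept = np.delete(pts, outliers, axis=0)
    return kept, outliers


def _robust_linear(x, y, robust: bool, residual_sigma: float = 1.5,
                   max_iter: int = 20):
    """OLS with optional iterative 1.5-sigma residual exclusion.

    Returns (slope, intercept, r2, inlier_mask, sm_result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.ones(x.size, dtype=bool)
    res = None
    for _ in range(max_iter if robust else 1):
        X = sm.add_constant(x[mask])
        res = sm.OLS(y[mask], X).fit()
        if not robust:
            break
        resid_all = y - (res.params[0] + res.params[1] * x)
        sd = resid_all[mask].std(ddof=1)
        # stop when residuals are at numerical-noise scale
        if sd <= 1e-9 * max(1.0, np.abs(y).max()):
            break
        new_mask = np.abs(resid_all) <= residual_sigma * sd
        if mask.sum() - new_mask.sum() <= 0 or new_mask.sum() < 3:
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return (float(res.params[1]), float(res.params[0]),
            float(res.rsquared), mask, res)


class MeanVarianceTrend(BaseEstimator, RegressorMixin):
    """Linear regression of variance on mean across conditions.

    scikit-learn style estimator: ``fit(X, y)`` with ``X`` the condition
    means (1-D or single column) and ``y`` the variances.  ``robust=True``
    iteratively excludes points with residuals beyond ``residual_sigma``
    standard deviations; ``mahalanobis_threshold`` (e.g. 0.05) applies a
    Mahalanobis pre-filter to the point cloud before fitting.

    Attributes: ``alpha_`` (slope), ``sigma0_`` (intercept), ``r2_``,
    ``outlier_indices_`` (original indices excluded by either rule),
    ``n_points_``, ``inlier_mask_``.
    """

    def __init__(self, robust: bool = True, residual_sigma: float = 1.5,
                 mahalanobis_threshold: Optional[float] = None,
                 max_iter: int = 20):
        self.robust = robust
        self.residual_sigma = residual_sigma
        self.mahalanobis_threshold = mahalanobis_threshold
        self.max_iter = max_iter

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x.ravel()
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("X must be 1-D means matching y (variances)")
        if x.size < 3:
            raise ValueError("need at least 3 (mean, variance) points")
        pre_mask = np.ones(x.size, dtype=bool)
        if self.mahalanobis_threshold is not None:
            _, out_idx = mahalanobis_filter(
                np.column_stack([x, y]), self.mahalanobis_threshold)
            pre_mask[out_idx] = False
        idx = np.nonzero(pre_mask)[0]
        slope, intercept, r2, sub_mask, res = _robust_linear(
            x[idx], y[idx], self.robust, self.residual_sigma, self.max_iter)
        inlier = np.zeros(x.size, dtype=bool)
        inlier[idx[sub_mask]] = True
        self.alpha_ = slope
        self.sigma0_ = intercept
        self.r2_ = r2
        self.inlier_mask_ = inlier
        self.outlier_indices_ = frozenset(np.nonzero(~inlier)[0].tolist())
        self.n_points_ = int(inlier.sum())
        self.X_ = x
        self.y_ = y
        self.result_ = res
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x.ravel()
        return self.alpha_ * x + self.sigma0_

    def to_trend(self) -> LinearTrend:
        return LinearTrend(alpha=self.alpha_, sigma0=self.sigma0_,
                           r2=self.r2_, n_points=self.n_points_,
                           outlier_indices=self.outlier_indices_)


def fit_mean_variance(summaries: Iterable[ConditionSummary],
                      robust: bool = True,
                      mahalanobis_threshold: Optional[float] = None
                      ) -> LinearTrend:
    """Fit sigma^2 = alpha mu + sigma0 over condition summaries."""
    summaries = list(summaries)
    means = np.array([s.mean for s in summaries])
    variances = np.array([s.variance for s in summaries])
    est = MeanVarianceTrend(robust=robust,
                            mahalanobis_threshold=mahalanobis_threshold)
    est.fit(means, variances)
    return est.to_trend()


def gene_filters(mean_table: pd.DataFrame, baseline: str,
                 min_fold: float = 2.0,
                 min_max_mean: float = 100.0) -> pd.Index:
    """Induction and abundance filters on a genes x conditions mean table.

    Keeps genes whose maximum condition mean reaches ``min_max_mean``
    *and* that are induced at least ``min_fold``-fold relative to the
    ``baseline`` (unstimulated) condition in some condition.  A zero
    baseline with nonzero response counts as induced.
    """
    mat = pd.DataFrame(mean_table)
    if baseline not in mat.columns:
        raise KeyError(f"baseline condition {baseline!r} not in table")
    base = mat[baseline].to_numpy(dtype=float)
    others = mat.drop(columns=[baseline]).to_numpy(dtype=float)
    peak = others.max(axis=1) if others.size else np.zeros(len(mat))
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(base > 0, peak / base,
                        np.where(peak > 0, np.inf, 0.0))
    max_mean = mat.to_numpy(dtype=float).max(axis=1)
    keep = (fold >= min_fold) & (max_mean >= min_max_mean)
    return mat.index[keep]


def burstiness_trends(summaries: Iterable[ConditionSummary],
                      robust: bool = True) -> Dict[TrendTarget, BurstTrendFit]:
    """Fit variance, relative burst-size and frequency trends vs mean.

    Variance and frequency are fitted linearly; burst size is fitted both
    linearly and in semilog scale (b against log10 mean) with the better
    R^2 retained.  Conditions whose moment burst size b_m <= 1 (infinite
    f_m) are skipped for the frequency trend with a warning.
    High-confidence flags use per-target R^2 thresholds
    (:data:`R2_THRESHOLDS`).
    """
    summaries = [s for s in summaries if s.mean > 0]
    mu = np.array([s.mean for s in summaries])
    var = np.array([s.variance for s in summaries])
    ests = [moment_estimators(s.mean, s.variance) for s in summaries]
    b = np.array([e.size for e in ests])
    f = np.array([e.frequency for e in ests])
    out: Dict[TrendTarget, BurstTrendFit] = {}

    def _fit(target, x, y, keep_idx):
        slope, intercept, r2, mask, _ = _robust_linear(x, y, robust)
        excluded = tuple(int(keep_idx[i]) for i in np.nonzero(~mask)[0])
        return slope, intercept, r2, excluded

    idx = np.arange(mu.size)
    s_, i_, r2, excl = _fit(TrendTarget.VARIANCE, mu, var, idx)
    out[TrendTarget.VARIANCE] = BurstTrendFit(
        TrendTarget.VARIANCE, TrendModel.LINEAR, (s_, i_), r2, excl,
        r2 > R2_THRESHOLDS[TrendTarget.VARIANCE])

    # burst size: choose the better of linear and semilog descriptions
    lin = _fit(TrendTarget.REL_BURST_SIZE, mu, b, idx)
    semi = _fit(TrendTarget.REL_BURST_SIZE, np.log10(mu), b, idx)
    if semi[2] > lin[2]:
        s_, i_, r2, excl = semi
        model = TrendModel.POWER_SEMILOG
    else:
        s_, i_, r2, excl = lin
        model = TrendModel.LINEAR
    out[TrendTarget.REL_BURST_SIZE] = BurstTrendFit(
        TrendTarget.REL_BURST_SIZE, model, (s_, i_), r2, excl,
        r2 > R2_THRESHOLDS[TrendTarget.REL_BURST_SIZE])

    finite = np.isfinite(f)
    if not finite.all():
        warnings.warn(f"{int((~finite).sum())} condition(s) with b_m <= 1 "
                      "(infinite frequency) skipped in frequency trend")
    if finite.sum() >= 3:
        s_, i_, r2, excl = _fit(TrendTarget.REL_FREQUENCY, mu[finite],
                                f[finite], idx[finite])
        out[TrendTarget.REL_FREQUENCY] = BurstTrendFit(
            TrendTarget.REL_FREQUENCY, TrendModel.LINEAR, (s_, i_), r2, excl,
            r2 > R2_THRESHOLDS[TrendTarget.REL_FREQUENCY])
    return out


def _xy_of(trend) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(trend, MeanVarianceTrend):
        m = trend.inlier_mask_
        return trend.X_[m], trend.y_[m]
    x, y = trend
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def compare_slopes(trend_a, trend_b) -> float:
    """p-value for a slope difference between two linear trends.

    Pools the two datasets and tests the group x slope interaction term
    of ``y ~ x * group`` with a t-test (fitted trends contribute their
    inlier points only).  Symmetric in its arguments.
    """
    xa, ya = _xy_of(trend_a)
    xb, yb = _xy_of(trend_b)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each trend needs at least 3 points")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    X = np.column_stack([np.ones(x.size), x, g, x * g])
    res = sm.OLS(y, X).fit()
    return float(res.pvalues[3])


def size_normalize(counts, nuclear_areas) -> np.ndarray:
    """Rescale per-cell counts by population-average over per-cell nuclear area.

    Removes the extrinsic count component proportional to cell size:
    ``count_i * mean(area) / area_i``.  Output is float (flagged as
    normalized, not raw integer counts).
    """
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(nuclear_areas, dtype=float)
    if counts.shape != areas.shape:
        raise ValueError("counts and areas must have the same length")
    if np.any(areas <= 0):
        raise ValueError("nuclear areas must be > 0")
    return counts * (areas.mean() / areas)
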
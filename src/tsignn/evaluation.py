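"""MCAR masking, normalization, baselines, and the twin evaluation protocol.

A complete dataset is evaluated by hiding 30% or 60% of its cells completely
at random, imputing, and scoring two ways:

* **RMSE on masked cells**, computed on the normalized scale (the output of
  the models is not renormalized or rounded);
* **congeniality** — R-squared of a downstream predictor (nonlinear
  gradient-boosted trees and ordinary least squares) fitted to impute-then-
  predict data versus the original complete data under an identical 70:30
  train/test split. A gap near zero means the imputation preserved the
  feature-label relationships.

Masking is applied on the source matrix *before* windowing so that every
window-copy of a cell shares its missingness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.impute import KNNImputer
from sklearn.linear_model import LinearRegression

from .series import TemporalSeries


@dataclass
class MissingnessMask:
    """Boolean T x F indicator of artificially hidden cells."""

    mask: np.ndarray
    rate: float
    seed: int
    label_protected: bool

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass
class NormalizationStats:
    """Per-feature location/scale fitted on observed cells.

    For min-max scaling to [0, 1] these are the feature minimum and maximum;
    for z-scoring the mean and mean+sd (so ``span`` is the sd either way).
    """

    minimum: np.ndarray
    maximum: np.ndarray
    method: str = "minmax"

    @property
    def span(self) -> np.ndarray:
        return self.maximum - self.minimum


@dataclass
class EvalReport:
    """One (method, rate, seed) cell of the evaluation grid."""

    method_name: str
    missing_rate: float
    split_seed: int
    rmse_masked: float
    r2_original: tuple[float, float] | None = None   # (nonlinear, linear)
    r2_imputed: tuple[float, float] | None = None

    @property
    def congeniality_gap(self) -> tuple[float, float] | None:
        if self.r2_original is None or self.r2_imputed is None:
            return None
        return (self.r2_imputed[0] - self.r2_original[0],
                self.r2_imputed[1] - self.r2_original[1])


def apply_mcar_mask(series: TemporalSeries, rate: float, seed: int,
                    label_protected: bool = True,
                    label_name: str | None = None
                    ) -> tuple[TemporalSeries, MissingnessMask]:
    """Hide each maskable cell independently with probability ``rate``.

    When ``label_protected`` and a label is named, its column is never masked
    so downstream R-squared measures feature-imputation quality only.
    """
    if not 0 < rate < 1:
        raise ValueError("missing rate must be in the open interval (0, 1)")
    rng = np.random.default_rng(seed)
    draw = rng.random(series.values.shape) < rate
    draw &= ~series.missing_mask  # only observed cells can be hidden
    if label_protected and label_name is not None:
        draw[:, series.feature_index(label_name)] = False
    masked = series.copy()
    masked.values[draw] = np.nan
    return masked, MissingnessMask(draw, rate, seed, label_protected)


def normalize(series: TemporalSeries,
              stats: NormalizationStats | None = None,
              method: str = "minmax"
              ) -> tuple[TemporalSeries, NormalizationStats]:
    """Per-feature scaling using observed cells only.

    ``minmax`` (default) scales to [0, 1]; ``zscore`` centers and scales by
    the observed standard deviation. Fitted stats can be reused on held-out
    data. A constant feature scales to 0 with a warning.
    """
    values = series.values
    if stats is None:
        if method not in ("minmax", "zscore"):
            raise ValueError("method must be 'minmax' or 'zscore'")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            if method == "minmax":
                mn = np.nanmin(values, axis=0)
                mx = np.nanmax(values, axis=0)
            else:
                mn = np.nanmean(values, axis=0)
                mx = mn + np.nanstd(values, axis=0)
        stats = NormalizationStats(mn, mx, method)
    span = stats.span.copy()
    constant = span == 0
    if np.any(constant):
        warnings.warn("constant feature(s) scaled to 0", stacklevel=2)
        span[constant] = 1.0
    scaled = series.copy()
    scaled.values = (values - stats.minimum) / span
    scaled.values[:, constant] = np.where(
        np.isnan(values[:, constant]), np.nan, 0.0)
    return scaled, stats


def denormalize(series: TemporalSeries,
                stats: NormalizationStats) -> TemporalSeries:
    """Inverse of :func:`normalize` (not applied before scoring)."""
    out = series.copy()
    span = np.where(stats.span == 0, 1.0, stats.span)
    out.values = series.values * span + stats.minimum
    return out


def rmse_masked(imputed: TemporalSeries, truth: TemporalSeries,
                mask: MissingnessMask) -> float:
    """Root mean squared error over the artificially masked cells only."""
    if imputed.values.shape != truth.values.shape:
        raise ValueError("imputed and truth shapes differ")
    cells = mask.mask
    if not cells.any():
        raise ValueError("mask hides no cells")
    diff = imputed.values[cells] - truth.values[cells]
    return float(np.sqrt(np.mean(diff * diff)))


def congeniality_eval(imputed: TemporalSeries, original: TemporalSeries,
                      label: str, split_ratio: float = 0.7, seed: int = 0,
                      time_ordered: bool = True
                      ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Downstream R-squared on imputed vs original data, identical split.

    Fits label ~ other features with gradient-boosted trees and with OLS on
    the train rows and scores R-squared on the test rows, for both datasets.
    The split is time-ordered by default (first 70% of rows train) to avoid
    leakage between adjacent rows; set ``time_ordered=False`` for a random
    split. Returns ``(r2_original, r2_imputed)``, each ``(nonlinear, linear)``.
    """
    j = original.feature_index(label)
    t = original.n_timesteps
    n_train = int(round(split_ratio * t))
    if time_ordered:
        train_idx = np.arange(n_train)
        test_idx = np.arange(n_train, t)
    else:
        perm = np.random.default_rng(seed).permutation(t)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    cols = [k for k in range(original.n_features) if k != j]

    def fit_score(data: TemporalSeries) -> tuple[float, float]:
        x, y = data.values[:, cols], data.values[:, j]
        if np.isnan(x).any() or np.isnan(y).any():
            raise ValueError("congeniality requires complete data")
        if np.var(y[test_idx]) == 0:
            raise ValueError("degenerate label variance in test split")
        gbr = GradientBoostingRegressor(random_state=seed)
        gbr.fit(x[train_idx], y[train_idx])
        lr = LinearRegression().fit(x[train_idx], y[train_idx])
        return (float(gbr.score(x[test_idx], y[test_idx])),
                float(lr.score(x[test_idx], y[test_idx])))

    return fit_score(original), fit_score(imputed)


# ---------------------------------------------------------------------------
# simple baselines

_INTERP_KIND = {"linear_interp": 1, "spline_interp": 2, "cubic_interp": 3}

BASELINE_METHODS = ("mean", "linear_interp", "spline_interp",
                    "cubic_interp", "knn")


def baseline_impute(series_masked: TemporalSeries, method: str,
                    knn_neighbors: int = 5) -> TemporalSeries:
    """Classic imputers: per-feature mean, temporal interpolation, KNN.

    Interpolation runs per feature along the time axis with boundary fill by
    the nearest observed value; KNN uses a distance-weighted average over the
    nearest rows (Euclidean on jointly observed features).
    """
    if method not in BASELINE_METHODS:
        raise ValueError(
            f"unknown method {method!r}; registered: {BASELINE_METHODS}")
    values = series_masked.values
    if np.isnan(values).all(axis=0).any():
        raise ValueError("a feature has zero observed values")
    out = series_masked.copy()
    if method == "mean":
        means = np.nanmean(values, axis=0)
        idx = np.where(np.isnan(values))
        out.values[idx] = means[idx[1]]
    elif method == "knn":
        imputer = KNNImputer(n_neighbors=knn_neighbors, weights="distance")
        out.values = imputer.fit_transform(values)
    else:
        from scipy.interpolate import make_interp_spline

        order = _INTERP_KIND[method]
        t = np.arange(values.shape[0])
        for j in range(values.shape[1]):
            col = values[:, j]
            observed = ~np.isnan(col)
            missing = ~observed
            k = min(order, observed.sum() - 1)
            inside = missing & (t > t[observed].min()) & (t < t[observed].max())
            if inside.any() and k >= 1:
                spline = make_interp_spline(t[observed], col[observed], k=k)
                out.values[inside, j] = spline(t[inside])
            # boundary fill by nearest observed value
            still = np.isnan(out.values[:, j])
            if still.any():
                obs_t = t[observed]
                nearest = obs_t[np.argmin(
                    np.abs(t[still][:, None] - obs_t[None, :]), axis=1)]
                out.values[still, j] = col[nearest]
    return out


# ---------------------------------------------------------------------------
# the experiment grid


def run_experiment(dataset: TemporalSeries, methods: list[str],
                   rates: tuple[float, ...] = (0.3, 0.6),
                   seeds: tuple[int, ...] = (0,),
                   label: str | None = None,
                   imputers: dict | None = None) -> pd.DataFrame:
    """mask -> normalize -> impute -> RMSE (+ congeniality) over a grid.

    ``imputers`` maps extra method names to callables
    ``f(scaled_masked: TemporalSeries, seed: int) -> TemporalSeries`` (used to
    plug in the graph imputers); baseline names resolve automatically.
    Returns a tidy DataFrame, one row per (method, rate, seed).
    """
    imputers = imputers or {}
    rows = []
    for rate in rates:
        for seed in seeds:
            masked, mask = apply_mcar_mask(dataset, rate, seed,
                                           label_protected=True,
                                           label_name=label)
            scaled_masked, stats = normalize(masked)
            scaled_truth, _ = normalize(dataset, stats)
            for method in methods:
                try:
                    if method in imputers:
                        imputed = imputers[method](scaled_masked, seed)
                    else:
                        imputed = baseline_impute(scaled_masked, method)
                    report = EvalReport(
                        method, rate, seed,
                        rmse_masked(imputed, scaled_truth, mask))
                    if label is not None:
                        r2_orig, r2_imp = congeniality_eval(
                            imputed, scaled_truth, label, seed=seed)
                        report.r2_original = r2_orig
                        report.r2_imputed = r2_imp
                except Exception as exc:  # record, keep the grid running
                    rows.append(dict(method=method, rate=rate, seed=seed,
                                     rmse=np.nan, error=f"{method}@{rate}: {exc}"))
                    continue
                row = dict(method=method, rate=rate, seed=seed,
                           rmse=report.rmse_masked, error="")
                if report.r2_original is not None:
                    row.update(r2_gbr_orig=report.r2_original[0],
                               r2_lr_orig=report.r2_original[1],
                               r2_gbr_imp=report.r2_imputed[0],
                               r2_lr_imp=report.r2_imputed[1])
                rows.append(row)
    return pd.DataFrame(rows)
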
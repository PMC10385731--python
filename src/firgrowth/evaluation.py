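"""Fit statistics, residual diagnostics and model comparison.

R² is reported as 1 − SSE/SST by default — the quantity consistent with
reading the statistic as "the model explains X% of the response variance".
The explained-variance ratio Σ(ŷ−ȳ)²/Σ(y−ȳ)², which can exceed 1 for biased
nonlinear predictors, is available via ``variant="explained"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import Dataset


@dataclass(frozen=True)
class Metrics:
    """R², RMSE and MAE for one model on one data split."""

    r2: float
    rmse: float
    mae: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae, "n": self.n}


def compute_metrics(observed, predicted, variant: str = "sse") -> Metrics:
    """R², RMSE, MAE of ``predicted`` against ``observed``.

    ``variant="sse"`` gives R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²; ``variant="explained"``
    gives Σ(ŷ−ȳ)²/Σ(y−ȳ)².  Zero variance in the observed vector makes R²
    undefined (NaN is returned and flagged by being NaN).
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("observed and predicted must be equal-length 1-d vectors")
    resid = y - yhat
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        r2 = float("nan")
    elif variant == "sse":
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst
    elif variant == "explained":
        r2 = float(np.sum((yhat - y.mean()) ** 2)) / sst
    else:
        raise ValueError(f"unknown R^2 variant {variant!r}")
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    return Metrics(r2=r2, rmse=rmse, mae=mae, n=y.size)


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def relative_change(reference: float, new: float, direction: str) -> float:
    """Percent improvement of ``new`` over ``reference``, one decimal.

    ``higher_better`` (R²): 100·(new−ref)/ref.  ``lower_better`` (RMSE, MAE):
    100·(ref−new)/ref.  Rounded half away from zero, matching the convention
    of reporting e.g. "RMSE decreased by 39.7%".
    """
    if reference == 0:
        raise ZeroDivisionError("reference metric is zero")
    if direction == "higher_better":
        pct = 100.0 * (new - reference) / reference
    elif direction == "lower_better":
        pct = 100.0 * (reference - new) / reference
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return _round_half_away(pct, 1)


@dataclass
class ResidualSummary:
    """Residuals with a binned-spread heteroscedasticity summary."""

    residuals: np.ndarray
    range: tuple[float, float]
    bin_edges: np.ndarray
    bin_means: np.ndarray
    bin_sds: np.ndarray
    bin_counts: np.ndarray

    @property
    def spread_ratio(self) -> float:
        """max bin sd / min bin sd; near 1 means homoscedastic."""
        positive = self.bin_sds[self.bin_sds > 0]
        if positive.size == 0:
            return 1.0
        return float(positive.max() / positive.min())


def residual_summary(predicted, observed, bins: int = 5) -> ResidualSummary:
    """Residual diagnostics binned by predicted value (equal-population bins).

    Bins whose population would be empty are merged with neighbours by the
    quantile construction (duplicate edges dropped).
    """
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    resid = y - yhat
    quantiles = np.linspace(0, 1, bins + 1)
    edges = np.unique(np.quantile(yhat, quantiles))
    if edges.size < 2:     # constant predictions: one bin
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    which = np.clip(np.searchsorted(edges, yhat, side="right") - 1,
                    0, edges.size - 2)
    means, sds, counts = [], [], []
    for b in range(edges.size - 1):
        r = resid[which == b]
        counts.append(r.size)
        means.append(float(r.mean()) if r.size else 0.0)
        sds.append(float(r.std(ddof=1)) if r.size > 1 else 0.0)
    return ResidualSummary(
        residuals=resid,
        range=(float(resid.min()), float(resid.max())),
        bin_edges=edges,
        bin_means=np.array(means), bin_sds=np.array(sds),
        bin_counts=np.array(counts))


def cv_group_importance(ds: Dataset, site_vars, clim_vars,
                        k: int = 10, seed: int = 0,
                        n_trees: int = 200) -> dict[str, float]:
    """K-fold cross-validated impurity importance summed by covariate group.

    A random forest is fitted on each training fold with all ladder inputs
    (T, N, site, climate); mean-decrease-in-impurity importances are averaged
    over folds, summed within the groups {T, Comp, Site, Clim} and scaled to
    percentages (sum 100).
    """
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.model_selection import KFold

    site_vars = list(site_vars)
    clim_vars = list(clim_vars)
    names = ["T", "N"] + site_vars + clim_vars
    frame = ds.to_frame()
    X = frame[names].to_numpy(dtype=float)
    y = ds.responses
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    importances = np.zeros(len(names))
    for fold, (train_idx, _) in enumerate(kf.split(X)):
        rf = RandomForestRegressor(n_estimators=n_trees,
                                   min_samples_leaf=5,
                                   random_state=seed + fold)
        rf.fit(X[train_idx], y[train_idx])
        importances += rf.feature_importances_
    importances /= k
    total = importances.sum()
    if total == 0:
        importances = np.full(len(names), 1.0 / len(names))
        total = 1.0
    share = dict(zip(names, importances / total * 100.0))
    return {
        "T": share["T"],
        "Comp": share["N"],
        "Site": sum(share[v] for v in site_vars),
        "Clim": sum(share[v] for v in clim_vars),
    }


def partial_dependence(predict, frame: pd.DataFrame, variable: str,
                       grid) -> pd.DataFrame:
    """Mean prediction as ``variable`` sweeps over ``grid``.

    ``predict`` maps a DataFrame of inputs to a prediction vector.  For each
    grid value the variable's column is overwritten and all other columns are
    left at their observed values; the curve is the mean prediction.
    """
    if variable not in frame.columns:
        raise KeyError(f"{variable!r} is not among predictor inputs")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    lo, hi = frame[variable].min(), frame[variable].max()
    if grid.min() < lo or grid.max() > hi:
        import warnings
        warnings.warn(f"partial-dependence grid for {variable} extends outside "
                      f"the observed range [{lo}, {hi}]", stacklevel=2)
    means = []
    for v in grid:
        modified = frame.copy()
        modified[variable] = v
        means.append(float(np.mean(predict(modified))))
    return pd.DataFrame({variable: grid, "mean_prediction": means})


@dataclass
class ComparisonReport:
    """Side-by-side test metrics for several methods on one split."""

    metrics: dict[str, Metrics]
    pairwise: pd.DataFrame          # relative changes, new vs reference
    winner: dict[str, str]          # best method per metric
    ties: list[str] = field(default_factory=list)


def compare_models(results: dict[str, Metrics]) -> ComparisonReport:
    """Compare methods (e.g. RP, BP, RF) evaluated on the same test split."""
    ns = {m.n for m in results.values()}
    if len(ns) > 1:
        raise ValueError(f"metrics computed on different splits (n = {sorted(ns)})")
    rows = []
    for ref_name, ref in results.items():
        for new_name, new in results.items():
            if ref_name == new_name:
                continue
            rows.append({
                "reference": ref_name, "model": new_name,
                "r2_change_pct": relative_change(ref.r2, new.r2, "higher_better"),
                "rmse_change_pct": relative_change(ref.rmse, new.rmse, "lower_better"),
                "mae_change_pct": relative_change(ref.mae, new.mae, "lower_better"),
            })
    pairwise = pd.DataFrame(rows)
    winner, ties = {}, []
    for metric, better in (("r2", max), ("rmse", min), ("mae", min)):
        values = {name: getattr(m, metric) for name, m in results.items()}
        best = better(values.values())
        best_names = sorted(n for n, v in values.items() if v == best)
        winner[metric] = best_names[0]
        if len(best_names) > 1:
            ties.append(metric)
    return ComparisonReport(metrics=results, pairwise=pairwise,
                            winner=winner, ties=ties)
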
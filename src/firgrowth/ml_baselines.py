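"""BP neural-network and random-forest growth models plus the covariate ladder.

The ladder is the nested model sequence

    rung 1  y = f(T)
    rung 2  y = f(T, Comp)
    rung 3  y = f(T, Comp, Site)
    rung 4  y = f(T, Comp, Site, Clim)

fitted with one shared 80/20 split so the marginal value of each covariate
group can be read off the test statistics, in the layout of the study's
sub-model tables.

The BP model is a three-layer feed-forward network (logistic hidden units,
identity output) trained by gradient backpropagation with learning rate
0.01, a target mean-squared-error of 0.001 on min–max-scaled data, and at
most 1000 epochs.  The random forest uses bootstrap-resampled regression
trees with ``mtry`` variables tried per split and mean-of-trees prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor

from .datamodel import Dataset, split_train_test
from .evaluation import Metrics, compute_metrics
from .feature_selection import STUDY_CLIM_VARS, STUDY_SITE_VARS
from .rp_model import fit_rp, rp_predict_dataset

RUNG_GROUPS = {1: ("T",), 2: ("T", "Comp"), 3: ("T", "Comp", "Site"),
               4: ("T", "Comp", "Site", "Clim")}


def hidden_nodes(n_in: int, n_out: int, m: int) -> int:
    """Hidden-layer size: floor(sqrt(n_in + n_out)) + m, m in [1, 10].

    The usual empirical sizing rule for a three-layer network; with 10
    inputs, 1 output and m = 3 it gives the 10:6:1 structure.
    """
    if n_in < 1 or n_out < 1:
        raise ValueError("layer sizes must be >= 1")
    if not 1 <= m <= 10:
        raise ValueError(f"m must be in [1, 10], got {m}")
    return int(math.floor(math.sqrt(n_in + n_out))) + m


@dataclass(frozen=True)
class SubModelSpec:
    """One rung of the ladder."""

    rung: int

    def __post_init__(self) -> None:
        if self.rung not in RUNG_GROUPS:
            raise ValueError("rung must be 1..4")

    @property
    def groups(self) -> tuple[str, ...]:
        return RUNG_GROUPS[self.rung]

    def variables(self, site_vars=STUDY_SITE_VARS,
                  clim_vars=STUDY_CLIM_VARS) -> list[str]:
        out = ["T"]
        if "Comp" in self.groups:
            out.append("N")
        if "Site" in self.groups:
            out.extend(site_vars)
        if "Clim" in self.groups:
            out.extend(clim_vars)
        return out


@dataclass(frozen=True)
class BPConfig:
    n_hidden: int | None = None        # None: sizing rule with m = 3
    learning_rate: float = 0.01
    target_loss: float = 0.001         # MSE on scaled outputs
    max_iter: int = 1000
    checkpoint_every: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hidden is not None and self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass(frozen=True)
class RFConfig:
    ntree: int = 160
    mtry: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")


class BPPredictor:
    """Trained three-layer network with frozen min–max scaling."""

    def __init__(self, mlp: MLPRegressor, feature_names: list[str],
                 x_min: np.ndarray, x_max: np.ndarray,
                 y_min: float, y_max: float,
                 loss_checkpoints: list[float]):
        self.mlp = mlp
        self.feature_names = feature_names
        self._x_min, self._x_max = x_min, x_max
        self._y_min, self._y_max = y_min, y_max
        self.loss_checkpoints = loss_checkpoints

    def _scale(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self._x_max > self._x_min,
                        self._x_max - self._x_min, 1.0)
        return (X - self._x_min) / span

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        X = frame[self.feature_names].to_numpy(dtype=float)
        scaled = self.mlp.predict(self._scale(X))
        return scaled * (self._y_max - self._y_min) + self._y_min

    def predict_dataset(self, ds: Dataset) -> np.ndarray:
        return self.predict_frame(ds.to_frame())


def train_bp(train: Dataset, spec: SubModelSpec, cfg: BPConfig = BPConfig(),
             site_vars=STUDY_SITE_VARS, clim_vars=STUDY_CLIM_VARS,
             ) -> BPPredictor:
    """Train the BP network for one ladder rung.

    Full-batch gradient descent, epoch by epoch, stopping when the training
    MSE on scaled data reaches ``target_loss`` or after ``max_iter`` epochs.
    Inputs and output are min–max scaled to [0, 1] with bounds frozen from
    the training split.
    """
    if len(train) < 50:
        raise ValueError("BP training needs at least 50 rows")
    names = spec.variables(site_vars, clim_vars)
    frame = train.to_frame()
    X = frame[names].to_numpy(dtype=float)
    y = train.responses
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    y_min, y_max = float(y.min()), float(y.max())
    span = np.where(x_max > x_min, x_max - x_min, 1.0)
    Xs = (X - x_min) / span
    ys = (y - y_min) / (y_max - y_min if y_max > y_min else 1.0)
    n_hidden = cfg.n_hidden or hidden_nodes(len(names), 1, 3)
    mlp = MLPRegressor(hidden_layer_sizes=(n_hidden,), activation="logistic",
                       solver="adam", learning_rate_init=cfg.learning_rate,
                       batch_size=min(len(ys), 200),
                       max_iter=1, warm_start=True, shuffle=True,
                       random_state=cfg.seed, tol=0.0, n_iter_no_change=10**9)
    checkpoints: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        for epoch in range(1, cfg.max_iter + 1):
            mlp.fit(Xs, ys)
            mse = float(np.mean((mlp.predict(Xs) - ys) ** 2))
            if not np.isfinite(mse):
                raise RuntimeError(f"training loss became non-finite at "
                                   f"epoch {epoch}")
            if epoch % cfg.checkpoint_every == 0 or epoch == 1:
                checkpoints.append(mse)
            if mse <= cfg.target_loss:
                checkpoints.append(mse)
                break
    return BPPredictor(mlp, names, x_min, x_max, y_min, y_max, checkpoints)


class RFPredictor:
    """Random forest with the trained feature list attached."""

    def __init__(self, rf: RandomForestRegressor, feature_names: list[str]):
        self.rf = rf
        self.feature_names = feature_names

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        return self.rf.predict(frame[self.feature_names].to_numpy(dtype=float))

    def predict_dataset(self, ds: Dataset) -> np.ndarray:
        return self.predict_frame(ds.to_frame())

    @property
    def feature_importances_(self) -> np.ndarray:
        return self.rf.feature_importances_


def train_rf(train: Dataset, spec: SubModelSpec, cfg: RFConfig = RFConfig(),
             site_vars=STUDY_SITE_VARS, clim_vars=STUDY_CLIM_VARS,
             ) -> RFPredictor:
    """Fit the random forest for one ladder rung."""
    if len(train) < 30:
        raise ValueError("RF training needs at least 30 rows")
    names = spec.variables(site_vars, clim_vars)
    if cfg.mtry > len(names):
        raise ValueError(f"mtry={cfg.mtry} exceeds the {len(names)} "
                         f"predictors of rung {spec.rung}")
    frame = train.to_frame()
    rf = RandomForestRegressor(n_estimators=cfg.ntree, max_features=cfg.mtry,
                               min_samples_leaf=5, bootstrap=True,
                               random_state=cfg.seed)
    rf.fit(frame[names].to_numpy(dtype=float), train.responses)
    return RFPredictor(rf, names)


#: the study's tuning grids: ntree = 1 then 20-step to 500; mtry = 1..10
NTREE_GRID_DEFAULT = (1,) + tuple(range(20, 501, 20))
MTRY_GRID_DEFAULT = tuple(range(1, 11))


def tune_rf(train: Dataset, spec: SubModelSpec,
            ntree_grid=NTREE_GRID_DEFAULT, mtry_grid=MTRY_GRID_DEFAULT,
            folds: int = 5, seed: int = 0,
            site_vars=STUDY_SITE_VARS, clim_vars=STUDY_CLIM_VARS,
            ) -> tuple[RFConfig, pd.DataFrame]:
    """Cross-validated RMSE over the (ntree, mtry) grid.

    Ties are broken toward the smaller ntree, then smaller mtry.
    """
    ntree_grid = [int(v) for v in ntree_grid]
    mtry_grid = [int(v) for v in mtry_grid]
    if not ntree_grid or not mtry_grid:
        raise ValueError("grids must be nonempty")
    names = spec.variables(site_vars, clim_vars)
    mtry_grid = [m for m in mtry_grid if m <= len(names)]
    if not mtry_grid:
        raise ValueError("every mtry in the grid exceeds the predictor count")
    frame = train.to_frame()
    X = frame[names].to_numpy(dtype=float)
    y = train.responses
    if folds > len(y):
        raise ValueError("fold count exceeds the number of rows")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    rows = []
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            sq_errors = []
            for train_idx, val_idx in splits:
                rf = RandomForestRegressor(
                    n_estimators=ntree, max_features=mtry,
                    min_samples_leaf=5, random_state=seed)
                rf.fit(X[train_idx], y[train_idx])
                sq_errors.append((rf.predict(X[val_idx]) - y[val_idx]) ** 2)
            rmse = float(np.sqrt(np.mean(np.concatenate(sq_errors))))
            rows.append({"ntree": ntree, "mtry": mtry, "cv_rmse": rmse})
    table = pd.DataFrame(rows)
    best = table.sort_values(["cv_rmse", "ntree", "mtry"]).iloc[0]
    return RFConfig(ntree=int(best["ntree"]), mtry=int(best["mtry"]),
                    seed=seed), table


@dataclass
class LadderRow:
    rung: int
    variables: list[str]
    train: Metrics
    test: Metrics
    predictor: object


@dataclass
class LadderResult:
    method: str
    rows: list[LadderRow]
    split_seed: int

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            records.append({
                "model": f"Sub-model {row.rung}" if row.rung < 4 else "Whole model",
                "variables": " + ".join(RUNG_GROUPS[row.rung]),
                "train_r2": row.train.r2, "train_mae": row.train.mae,
                "train_rmse": row.train.rmse,
                "test_r2": row.test.r2, "test_mae": row.test.mae,
                "test_rmse": row.test.rmse,
            })
        return pd.DataFrame(records)

    def test_metrics(self, rung: int) -> Metrics:
        return next(r.test for r in self.rows if r.rung == rung)


def run_ladder(method: str, ds: Dataset, seed: int = 0,
               site_vars=STUDY_SITE_VARS, clim_vars=STUDY_CLIM_VARS,
               bp_config: BPConfig | None = None,
               rf_config: RFConfig | None = None) -> LadderResult:
    """Fit all four rungs with one shared 80/20 split and tabulate metrics.

    ``method`` is "RP" (re-parameterized Mitscherlich), "BP" or "RF".  For
    the forest, ``mtry`` is capped at each rung's predictor count so the
    whole-model default (mtry = 4) remains usable on the age-only rung.
    """
    if method not in ("RP", "BP", "RF"):
        raise ValueError(f"unknown method {method!r}")
    train, test = split_train_test(ds, 0.8, seed=seed)
    rows: list[LadderRow] = []
    for rung in (1, 2, 3, 4):
        spec = SubModelSpec(rung)
        names = spec.variables(site_vars, clim_vars)
        if method == "RP":
            covariates = [v for v in names if v != "T"]
            fit = fit_rp(train, covariates, seed=seed)
            predictor = fit.coefficients
            train_pred = rp_predict_dataset(predictor, train)
            test_pred = rp_predict_dataset(predictor, test)
        elif method == "BP":
            cfg = bp_config or BPConfig(seed=seed)
            predictor = train_bp(train, spec, cfg, site_vars, clim_vars)
            train_pred = predictor.predict_dataset(train)
            test_pred = predictor.predict_dataset(test)
        else:
            cfg = rf_config or RFConfig(seed=seed)
            cfg = RFConfig(ntree=cfg.ntree, mtry=min(cfg.mtry, len(names)),
                           seed=cfg.seed)
            predictor = train_rf(train, spec, cfg, site_vars, clim_vars)
            train_pred = predictor.predict_dataset(train)
            test_pred = predictor.predict_dataset(test)
        rows.append(LadderRow(
            rung=rung, variables=names,
            train=compute_metrics(train.responses, train_pred),
            test=compute_metrics(test.responses, test_pred),
            predictor=predictor))
    return LadderResult(method=method, rows=rows, split_seed=seed)
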
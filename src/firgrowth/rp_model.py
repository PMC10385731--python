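"""Re-parameterized Mitscherlich growth model (the RP model).

The age-only Mitscherlich curve y = a·(1 − e^(−b·T)) is re-parameterized by
expressing its asymptote and rate as linear combinations of plot covariates:

    ω0 = α0 + α1·x1 + … + αp·xp        (response units)
    ω1 = β0 + β1·x1 + … + βp·xp        (per year)
    y  = ω0 · (1 − e^(−ω1·T))

with the default covariate list N (stand density), PW (slope position),
HB (elevation), TRHD (soil thickness), DM (landform), DD18 (degree-days
above 18 °C) and Eref (reference evaporation).  The module also provides the
multicollinearity screen (VIF) and AIC-based stepwise selection used to
arrive at that list, and nonlinear least-squares fitting of the α/β vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .base_growth import fit_curve
from .datamodel import CovariateVector, Dataset
from .evaluation import Metrics, compute_metrics

#: Covariates of the published DBH/H models, in reporting order.
DEFAULT_RP_VARIABLES = ("N", "PW", "HB", "TRHD", "DM", "DD18", "Eref")

VIF_THRESHOLD = 5.0


@dataclass(frozen=True)
class RPCoefficients:
    """α/β vectors tied to named covariates.

    ``alpha[0]``/``beta[0]`` are the intercepts α0/β0; ``alpha[i]`` is the
    coefficient of ``variable_names[i-1]`` in ω0 (response units per
    covariate unit), ``beta[i]`` the same in ω1 (per-year rate per unit).
    """

    variable_names: tuple[str, ...]
    alpha: tuple[float, ...]
    beta: tuple[float, ...]
    response_kind: str = "DBH"

    def __post_init__(self) -> None:
        expected = len(self.variable_names) + 1
        if len(self.alpha) != expected or len(self.beta) != expected:
            raise ValueError(
                f"alpha/beta must have length {expected} "
                f"(intercept + one per variable)")

    def as_dict(self) -> dict:
        return {
            "response_kind": self.response_kind,
            "variables": list(self.variable_names),
            "alpha": {"intercept": self.alpha[0],
                      **dict(zip(self.variable_names, self.alpha[1:]))},
            "beta": {"intercept": self.beta[0],
                     **dict(zip(self.variable_names, self.beta[1:]))},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RPCoefficients":
        names = tuple(payload["variables"])
        alpha = (payload["alpha"]["intercept"],
                 *(payload["alpha"][v] for v in names))
        beta = (payload["beta"]["intercept"],
                *(payload["beta"][v] for v in names))
        return cls(names, tuple(float(a) for a in alpha),
                   tuple(float(b) for b in beta),
                   payload.get("response_kind", "DBH"))


def load_coefficients(name: str) -> RPCoefficients:
    """Load a shipped coefficient fixture (``table1_dbh`` or ``table4_h``)
    or a JSON file path produced by :meth:`RPCoefficients.as_dict`."""
    fixture = resources.files("firgrowth.fixtures").joinpath(f"{name}.json")
    if fixture.is_file():
        payload = json.loads(fixture.read_text())
    else:
        with open(name) as fh:
            payload = json.load(fh)
    return RPCoefficients.from_dict(payload)


class OmegaPair(NamedTuple):
    omega0: float
    omega1: float
    valid: bool          # both strictly positive


def omega_pair(coeffs: RPCoefficients, cov: CovariateVector) -> OmegaPair:
    """Evaluate ω0 and ω1 for one covariate vector.

    Non-positive values are returned as-is with ``valid=False`` — they arise
    for covariate combinations outside the model's calibration envelope.
    """
    if tuple(cov.names) != tuple(coeffs.variable_names):
        raise ValueError(
            f"covariate names {cov.names} do not match coefficient "
            f"variables {coeffs.variable_names}")
    x = np.asarray(cov.values, dtype=float)
    w0 = float(coeffs.alpha[0] + np.dot(coeffs.alpha[1:], x))
    w1 = float(coeffs.beta[0] + np.dot(coeffs.beta[1:], x))
    return OmegaPair(w0, w1, w0 > 0 and w1 > 0)


def rp_predict(coeffs: RPCoefficients, cov: CovariateVector, T) -> float | np.ndarray:
    """ω0·(1 − e^(−ω1·T)) at age(s) ``T`` (years, >= 0)."""
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("age T must be >= 0")
    w0, w1, _ = omega_pair(coeffs, cov)
    value = w0 * (1.0 - np.exp(-w1 * T))
    return value if value.ndim else float(value)


def rp_predict_matrix(coeffs: RPCoefficients, X: np.ndarray,
                      T: np.ndarray) -> np.ndarray:
    """Vectorized prediction: one row of ``X`` (ordered like
    ``coeffs.variable_names``) and one age per observation."""
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    w0 = coeffs.alpha[0] + X @ np.asarray(coeffs.alpha[1:])
    w1 = coeffs.beta[0] + X @ np.asarray(coeffs.beta[1:])
    return w0 * (1.0 - np.exp(-w1 * T))


def rp_predict_dataset(coeffs: RPCoefficients, ds: Dataset) -> np.ndarray:
    X = ds.covariate_matrix(list(coeffs.variable_names))
    return rp_predict_matrix(coeffs, X, ds.ages)


# ---------------------------------------------------------------------------
# Multicollinearity screening
# ---------------------------------------------------------------------------

def vif_table(X: np.ndarray, names: Sequence[str] | None = None) -> dict[str, float]:
    """Variance inflation factor of each column: VIF_j = 1/(1 − R²_j),
    R²_j from regressing column j on the others plus an intercept.

    Perfectly collinear columns get ``inf``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    if n <= p:
        raise ValueError("VIF needs more rows than columns")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out: dict[str, float] = {}
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            out[names[j]] = float("inf")
            continue
        r2 = 1.0 - float(np.sum(resid ** 2)) / sst
        out[names[j]] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(X: np.ndarray, names: Sequence[str] | None = None,
               threshold: float = VIF_THRESHOLD) -> list[str]:
    """Iteratively drop the max-VIF column until all VIF < ``threshold``.

    Survivors are returned in their original order; a tie on the maximum is
    broken by dropping the later-listed column.
    """
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    keep = list(range(X.shape[1]))
    while len(keep) >= 2:
        table = vif_table(X[:, keep], [names[j] for j in keep])
        values = np.array(list(table.values()))
        worst = float(np.max(values))
        if worst < threshold:
            break
        # later-listed column wins a tie for the maximum
        drop_pos = max(i for i, v in enumerate(values) if v == worst)
        keep.pop(drop_pos)
    return [names[j] for j in keep]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class RPFit:
    coefficients: RPCoefficients
    train_metrics: Metrics
    converged: bool
    sse: float
    message: str = ""


def _design(ds: Dataset, variables: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = ds.covariate_matrix(list(variables))
    return X, ds.ages, ds.responses


def fit_rp(train: Dataset, variables: Sequence[str] = DEFAULT_RP_VARIABLES,
           base: str = "Mitscherlich", n_restarts: int = 5, seed: int = 0,
           ) -> RPFit:
    """Nonlinear least-squares fit of the α/β coefficient vectors.

    Covariates are standardized internally for optimization and the
    coefficients back-transformed to raw scale for reporting.  Initialization
    comes from the age-only base fit (α0 ← â, β0 ← b̂, all covariate
    coefficients 0); bounded multi-start precedes a non-convergence flag.
    With ``variables=[]`` the fit reduces exactly to the base Mitscherlich
    model.
    """
    variables = list(variables)
    p = len(variables)
    n_min = 2 * (p + 1) + 2
    if len(train) < n_min:
        raise ValueError(f"need at least {n_min} observations for "
                         f"{p} covariates, got {len(train)}")
    if base != "Mitscherlich":
        raise NotImplementedError("only the Mitscherlich base is re-parameterized")
    X, T, y = _design(train, variables)
    mu = X.mean(axis=0) if p else np.zeros(0)
    sigma = X.std(axis=0, ddof=0) if p else np.zeros(0)
    sigma = np.where(sigma > 0, sigma, 1.0)
    Z = (X - mu) / sigma if p else X

    base_fit = fit_curve("Mitscherlich", train, seed=seed)
    theta0 = np.zeros(2 * (p + 1))
    theta0[0] = base_fit.curve.a
    theta0[p + 1] = base_fit.curve.b

    def residuals(theta: np.ndarray) -> np.ndarray:
        A, B = theta[:p + 1], theta[p + 1:]
        w0 = A[0] + (Z @ A[1:] if p else 0.0)
        w1 = B[0] + (Z @ B[1:] if p else 0.0)
        return w0 * (1.0 - np.exp(-w1 * T)) - y

    rng = np.random.default_rng(seed)
    best = None
    converged = False
    for attempt in range(n_restarts):
        start = theta0.copy()
        if attempt:
            start[0] *= rng.lognormal(0.0, 0.2)
            start[p + 1] *= rng.lognormal(0.0, 0.2)
            start[1:p + 1] = rng.normal(0.0, 0.05 * abs(theta0[0]) + 1e-3, p)
        sol = least_squares(residuals, start, method="trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            converged = True
            break
    assert best is not None
    A, B = best.x[:p + 1], best.x[p + 1:]
    # back-transform from standardized to raw covariate scale
    alpha = np.empty(p + 1)
    beta = np.empty(p + 1)
    alpha[1:] = A[1:] / sigma
    beta[1:] = B[1:] / sigma
    alpha[0] = A[0] - float(np.dot(A[1:], mu / sigma)) if p else A[0]
    beta[0] = B[0] - float(np.dot(B[1:], mu / sigma)) if p else B[0]
    coeffs = RPCoefficients(tuple(variables), tuple(alpha), tuple(beta),
                            train.response_kind)
    pred = rp_predict_dataset(coeffs, train)
    return RPFit(coefficients=coeffs,
                 train_metrics=compute_metrics(y, pred),
                 converged=converged,
                 sse=float(np.sum((pred - y) ** 2)),
                 message="" if converged else "did not converge")


# ---------------------------------------------------------------------------
# Stepwise AIC selection
# ---------------------------------------------------------------------------

def _aic(sse: float, n: int, k: int) -> float:
    sse = max(sse, 1e-300)
    return n * np.log(sse / n) + 2 * k


def stepwise_aic(train: Dataset, candidates: Iterable[str],
                 seed: int = 0, max_steps: int = 50,
                 verbose: bool = False) -> list[str]:
    """Both-direction stepwise search over the RP model's covariate set.

    A variable enters or leaves ω0 and ω1 together (the published model uses
    one shared variable list).  The criterion is AIC = n·ln(SSE/n) + 2k with
    k the number of free α/β coefficients, evaluated by refitting the
    nonlinear model for every candidate move.  Returns the AIC-minimizing
    set in candidate order; empty if nothing improves on the age-only model.
    """
    candidates = list(candidates)
    n = len(train)
    cache: dict[tuple[str, ...], float] = {}

    def score(subset: tuple[str, ...]) -> float:
        if subset not in cache:
            fit = fit_rp(train, list(subset), n_restarts=2, seed=seed)
            cache[subset] = _aic(fit.sse, n, 2 * (len(subset) + 1))
        return cache[subset]

    current: tuple[str, ...] = ()
    if not candidates:
        return []
    current_aic = score(current)
    for _ in range(max_steps):
        moves: list[tuple[float, tuple[str, ...]]] = []
        for v in candidates:
            if v in current:
                moves.append((score(tuple(x for x in current if x != v)),
                              tuple(x for x in current if x != v)))
            else:
                added = tuple(x for x in candidates if x in current or x == v)
                moves.append((score(added), added))
        best_aic, best_set = min(moves, key=lambda m: m[0])
        if best_aic < current_aic - 1e-9:
            current, current_aic = best_set, best_aic
            if verbose:
                print(f"step -> {list(current)} (AIC {current_aic:.2f})")
        else:
            break
    return list(current)
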
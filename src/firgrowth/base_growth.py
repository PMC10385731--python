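"""Age-only candidate growth equations and base-model selection.

Four classical bounded growth curves are fitted to response-vs-age data by
nonlinear least squares and ranked; the winner becomes the base model whose
parameters are later re-parameterized on covariates.

family        equation
------------  -----------------------------
Gompertz      y = a * exp(-b * exp(-c*t))
Logistic      y = a / (1 + b * exp(-c*t))
Mitscherlich  y = a * (1 - exp(-b*t))
Richards      y = a * (1 - exp(-c*t))**b
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datamodel import Dataset
from .evaluation import Metrics, compute_metrics

FAMILIES = ("Gompertz", "Logistic", "Mitscherlich", "Richards")

#: number of free parameters per family
N_PARAMS = {"Gompertz": 3, "Logistic": 3, "Mitscherlich": 2, "Richards": 3}


@dataclass(frozen=True)
class GrowthCurve:
    family: str
    a: float
    b: float
    c: float = 0.0           # unused by Mitscherlich

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.a <= 0:
            raise ValueError("asymptote a must be > 0")


def curve_value(curve: GrowthCurve, t) -> np.ndarray | float:
    """Evaluate the family's closed form at age ``t`` (years, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age t must be >= 0")
    a, b, c = curve.a, curve.b, curve.c
    if curve.family == "Gompertz":
        value = a * np.exp(-b * np.exp(-c * t))
    elif curve.family == "Logistic":
        value = a / (1.0 + b * np.exp(-c * t))
    elif curve.family == "Mitscherlich":
        value = a * (1.0 - np.exp(-b * t))
    else:  # Richards
        value = a * (1.0 - np.exp(-c * t)) ** b
    return value if value.ndim else float(value)


def _initial_guess(family: str, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Start values: a0 slightly above the observed maximum, rate from a
    log-linearization of the curve, shape parameters at 1."""
    a0 = 1.05 * float(y.max())
    inner = np.clip(1.0 - y / a0, 1e-9, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = float(np.median(-np.log(inner) / np.maximum(t, 1e-9)))
    rate = rate if np.isfinite(rate) and rate > 0 else 0.05
    if family == "Mitscherlich":
        return np.array([a0, rate])
    if family == "Richards":
        return np.array([a0, 1.0, rate])
    return np.array([a0, 1.0, rate])   # Gompertz / Logistic: b0 = 1


def _pack(family: str, params: np.ndarray) -> GrowthCurve:
    if family == "Mitscherlich":
        return GrowthCurve(family, a=float(params[0]), b=float(params[1]))
    if family == "Richards":
        return GrowthCurve(family, a=float(params[0]), b=float(params[1]),
                           c=float(params[2]))
    return GrowthCurve(family, a=float(params[0]), b=float(params[1]),
                       c=float(params[2]))


@dataclass
class CurveFit:
    curve: GrowthCurve
    train_metrics: Metrics
    converged: bool
    message: str = ""
    degenerate: bool = False      # e.g. near-zero rate on constant data


def fit_curve(family: str, train: Dataset, n_restarts: int = 5,
              seed: int = 0) -> CurveFit:
    """Least-squares fit of one family to response vs age.

    Bounded multi-start: the log-linearized start plus seeded perturbations;
    non-convergence is flagged on the result (best-so-far parameters are
    still returned), never silently ignored.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    t = train.ages
    y = train.responses
    k = N_PARAMS[family]
    if y.size < k + 1:
        raise ValueError(f"{family} needs at least {k + 1} observations, "
                         f"got {y.size}")

    def residuals(params: np.ndarray) -> np.ndarray:
        return curve_value(_pack(family, params), t) - y

    lower = np.full(k, 1e-8)
    upper = np.full(k, np.inf)
    base_start = _initial_guess(family, t, y)
    rng = np.random.default_rng(seed)
    best = None
    converged = False
    message = ""
    for attempt in range(n_restarts):
        start = base_start if attempt == 0 else np.clip(
            base_start * rng.lognormal(0.0, 0.4, size=k), lower, None)
        try:
            sol = least_squares(residuals, start, bounds=(lower, upper),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:          # singular jacobian etc.
            message = str(exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            converged = True
            if best.cost <= sol.cost * (1 + 1e-9):
                break
    if best is None:
        raise RuntimeError(f"{family}: optimizer failed on every start "
                           f"({message})")
    curve = _pack(family, best.x)
    pred = curve_value(curve, t)
    rate = curve.b if family == "Mitscherlich" else curve.c
    degenerate = rate < 1e-6 or np.std(y) == 0
    return CurveFit(curve=curve, train_metrics=compute_metrics(y, pred),
                    converged=converged,
                    message="" if converged else "did not converge",
                    degenerate=degenerate)


@dataclass
class RankedCurve:
    family: str
    fit: CurveFit
    test_metrics: Metrics


def select_base(families, train: Dataset, test: Dataset,
                seed: int = 0) -> tuple[list[RankedCurve], list[str]]:
    """Fit every family and rank by test R² (desc), then RMSE, then parsimony.

    Returns the ranked convergent fits and the names of families that failed
    to converge (listed separately, as a Richards fit on real inventory data
    often does).
    """
    ranked: list[RankedCurve] = []
    failed: list[str] = []
    for family in families:
        try:
            fit = fit_curve(family, train, seed=seed)
        except (RuntimeError, ValueError):
            failed.append(family)
            continue
        if not fit.converged:
            failed.append(family)
            continue
        pred = curve_value(fit.curve, test.ages)
        ranked.append(RankedCurve(family, fit, compute_metrics(test.responses, pred)))
    if not ranked:
        raise RuntimeError("no growth-curve family converged")
    ranked.sort(key=lambda r: (-round(r.test_metrics.r2, 12),
                               round(r.test_metrics.rmse, 12),
                               N_PARAMS[r.family]))
    return ranked, failed
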
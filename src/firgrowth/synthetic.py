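"""Synthetic continuous-forest-inventory generator with known ground truth.

Because the CFI survey data behind the Chinese-fir study are not public, all
downstream stages are exercised on simulated inventories that mimic the
published data description: square ~667 m² plots remeasured at 5-year
intervals, site factors in the published ranges with the Fujian coding
scheme, 17 annual climate variables with a correlated warm/wet structure
(MAT strongly tied to MCMT, Eref and MAP; MCMT to DD18 and Eref), and
responses drawn from the re-parameterized Mitscherlich law plus Gaussian
noise.

The default generating coefficients are a documented synthetic truth (see
``docs/methods.md``): the re-parameterized model's seven covariates plus
small real effects for slope aspect (PX) and precipitation (MAP), with
standardized effect sizes chosen so the variable-importance structure of the
simulated data matches the study system (slope position dominating the site
group, heat sum dominating the climate group).  The published Table-style
coefficient fixtures remain available and can be passed in explicitly for
parameter-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .datamodel import (DM_CODES, PW_CODES, PX_CODES, TRMC_CODES,
                        ClimateFactors, Dataset, PlotRecord, SiteFactors,
                        TreeObservation)
from .rp_model import RPCoefficients, rp_predict_matrix

#: 17 annual climate variables: the five the study highlights plus twelve
#: further ClimateAP-style annual variables treated as inert background.
CLIMATE_RANGES_DEFAULT: dict[str, tuple[float, float]] = {
    "DD18": (300.0, 2500.0),   # degree-days above 18 degC
    "MAP": (1400.0, 2000.0),   # mean annual precipitation, mm
    "Eref": (600.0, 1100.0),   # Hargreaves reference evaporation, mm
    "MAT": (17.0, 21.0),       # mean annual temperature, degC
    "MCMT": (6.0, 12.0),       # mean coldest-month temperature, degC
    "MWMT": (24.0, 30.0),
    "TD": (10.0, 16.0),
    "MSP": (500.0, 900.0),
    "AHM": (25.0, 45.0),
    "SHM": (60.0, 120.0),
    "DD5": (5000.0, 7500.0),
    "NFFD": (300.0, 365.0),
    "PAS": (0.0, 5.0),
    "EMT": (-8.0, 0.0),
    "EXT": (33.0, 41.0),
    "CMD": (0.0, 200.0),
    "RH": (70.0, 85.0),
}

_STRONG_PAIRS = {
    ("MAT", "MCMT"): 0.85, ("MAT", "Eref"): 0.76, ("MAT", "MAP"): 0.76,
    ("MCMT", "DD18"): 0.76, ("MCMT", "Eref"): 0.76,
    # weaker fill-in keeping the matrix positive semi-definite
    ("MAT", "DD18"): 0.50, ("MCMT", "MAP"): 0.45, ("DD18", "Eref"): 0.40,
    ("DD18", "MAP"): 0.35, ("Eref", "MAP"): 0.40,
}


def default_climate_correlation(names=None) -> pd.DataFrame:
    """Correlation matrix mimicking a subtropical warm/wet climate gradient."""
    if names is None:
        names = list(CLIMATE_RANGES_DEFAULT)
    R = np.eye(len(names))
    index = {n: i for i, n in enumerate(names)}
    for (a, b), r in _STRONG_PAIRS.items():
        if a in index and b in index:
            R[index[a], index[b]] = R[index[b], index[a]] = r
    return pd.DataFrame(R, index=list(names), columns=list(names))


#: Synthetic generating truth for DBH (cm): mean asymptote 22 cm, constant
#: age rate 0.045/yr.  Per-covariate coefficients correspond to these
#: standardized asymptote contributions (effect x covariate sd over its
#: default range, cm): DD18 3.8, PW 3.0, HB 2.2, MAP 1.7, TRHD 1.7, PX 1.6,
#: DM 1.4, Eref 1.1, N 0.8 — sized so the variable-importance structure of
#: simulated inventories mirrors the study system (slope position leading
#: the site group, heat sum the climate group, with MAT/MCMT influential
#: only through correlation).
TRUTH_DBH = RPCoefficients(
    variable_names=("N", "PW", "HB", "TRHD", "DM", "PX", "DD18", "Eref", "MAP"),
    alpha=(-28.1351, -0.013937, -1.75644, -0.009709, 0.125276, -1.715686,
           0.698385, 0.010363, 0.013205, 0.017),
    beta=(0.045, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    response_kind="DBH",
)

#: Synthetic generating truth for height (m): mean asymptote 14 m, rate
#: 0.05/yr; same contribution structure as DBH at half the (1 m noise) scale.
TRUTH_H = RPCoefficients(
    variable_names=("N", "PW", "HB", "TRHD", "DM", "PX", "DD18", "Eref", "MAP"),
    alpha=(-9.2379, -0.005391, -0.87822, -0.004053, 0.042079, -0.857843,
           0.349192, 0.005181, 0.006603, 0.0085),
    beta=(0.05, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    response_kind="H",
)

#: Published covariate ranges (site and tree variables) per response kind.
SITE_RANGES = {
    "DBH": {"N": (40, 238), "HB": (100.0, 885.0), "PD": (2.0, 35.0),
            "TRHD": (73.0, 120.0)},
    "H": {"N": (25, 282), "HB": (101.0, 1041.0), "PD": (5.0, 37.0),
          "TRHD": (60.0, 130.0)},
}

#: First-survey age windows keeping all survey ages within the published
#: overall age ranges ([4, 41] for DBH over 4 surveys, [4, 51] for H over 3).
FIRST_AGE = {"DBH": (4, 26), "H": (4, 41)}


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the simulator (defaults = the emulated study)."""

    response_kind: str = "DBH"
    n_plots: int = 800
    trees_per_plot: int = 3
    surveys_per_tree: int = 4          # 3 for H
    survey_interval: int = 5           # years
    first_age_range: tuple[int, int] = FIRST_AGE["DBH"]
    age_structure: str = "even"        # "even": plot age +- jitter; "mixed"
    age_jitter: int = 3
    ranges: dict = field(default_factory=lambda: dict(SITE_RANGES["DBH"]))
    climate_ranges: dict = field(
        default_factory=lambda: dict(CLIMATE_RANGES_DEFAULT))
    climate_correlation: pd.DataFrame = field(
        default_factory=default_climate_correlation)
    coefficients: RPCoefficients = TRUTH_DBH
    noise_sd: float = 2.0              # cm for DBH, m for H
    response_floor: float = 0.1
    base_year: int = 1993
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (lo, hi) in {**self.ranges, **self.climate_ranges}.items():
            if lo > hi:
                raise ValueError(f"range for {name} has min > max")
        R = self.climate_correlation
        if list(R.index) != list(self.climate_ranges):
            self.climate_correlation = R = R.reindex(
                index=list(self.climate_ranges),
                columns=list(self.climate_ranges)).fillna(0.0)
            np.fill_diagonal(self.climate_correlation.values, 1.0)
        A = R.to_numpy()
        if not np.allclose(A, A.T) or not np.allclose(np.diag(A), 1.0):
            raise ValueError("climate correlation must be symmetric with "
                             "unit diagonal")
        if np.linalg.eigvalsh(A).min() < -1e-8:
            raise ValueError("climate correlation matrix is not positive "
                             "semi-definite")

    @classmethod
    def for_height(cls, **overrides) -> "GeneratorConfig":
        base = dict(response_kind="H", surveys_per_tree=3,
                    first_age_range=FIRST_AGE["H"],
                    ranges=dict(SITE_RANGES["H"]),
                    coefficients=TRUTH_H, noise_sd=1.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if payload.get("response_kind") == "H":
            payload.pop("response_kind")
            return cls.for_height(**_decode(payload))
        return cls(**_decode(payload))

    def with_(self, **overrides) -> "GeneratorConfig":
        return replace(self, **overrides)


def _decode(payload: dict) -> dict:
    payload = dict(payload)
    if "coefficients" in payload:
        payload["coefficients"] = RPCoefficients.from_dict(payload["coefficients"])
    if "climate_correlation" in payload:
        payload["climate_correlation"] = pd.DataFrame(payload["climate_correlation"])
    for key in ("ranges", "climate_ranges"):
        if key in payload:
            payload[key] = {k: tuple(v) for k, v in payload[key].items()}
    return payload


def _sample_plot(cfg: GeneratorConfig, rng: np.random.Generator,
                 plot_id: str) -> PlotRecord:
    r = cfg.ranges
    lo, hi = r["N"]
    n_stems = int(rng.integers(int(lo), int(hi) + 1))
    site = SiteFactors(
        HB=float(rng.uniform(*r["HB"])),
        PD=float(rng.uniform(*r["PD"])),
        TRHD=float(rng.uniform(*r["TRHD"])),
        DM=int(rng.choice(sorted(DM_CODES))),
        PX=int(rng.choice(sorted(PX_CODES))),
        PW=int(rng.choice(sorted(PW_CODES))),
        TRMC=int(rng.choice(sorted(TRMC_CODES))),
    )
    names = list(cfg.climate_ranges)
    lows = np.array([cfg.climate_ranges[n][0] for n in names])
    highs = np.array([cfg.climate_ranges[n][1] for n in names])
    mean = (lows + highs) / 2.0
    sd = np.where(highs > lows, (highs - lows) / 6.0, 0.0)
    cov = np.outer(sd, sd) * cfg.climate_correlation.to_numpy()
    draw = rng.multivariate_normal(mean, cov, method="svd")
    draw = np.clip(draw, lows, highs)
    climate = ClimateFactors(dict(zip(names, map(float, draw))))
    return PlotRecord(plot_id=plot_id, N=n_stems, site=site, climate=climate)


def generate_plots(cfg: GeneratorConfig,
                   rng: np.random.Generator | None = None) -> list[PlotRecord]:
    """Sample plot records: uniform site factors (independent of each other),
    uniform codes, and a correlated multivariate climate draw clipped to its
    ranges."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    width = max(3, len(str(cfg.n_plots)))
    return [_sample_plot(cfg, rng, f"P{i + 1:0{width}d}")
            for i in range(cfg.n_plots)]


def _plot_omegas(cfg: GeneratorConfig, plot: PlotRecord) -> tuple[float, float]:
    coeffs = cfg.coefficients
    x = np.array([plot.covariate(v) for v in coeffs.variable_names])
    w0 = coeffs.alpha[0] + float(np.dot(coeffs.alpha[1:], x))
    w1 = coeffs.beta[0] + float(np.dot(coeffs.beta[1:], x))
    return w0, w1


def generate_observations(plots: list[PlotRecord],
                          cfg: GeneratorConfig) -> Dataset:
    """Simulate repeated surveys of every tree under the generating RP law.

    Responses are ω0·(1−e^(−ω1·T)) plus Gaussian noise, floored at a small
    positive value.  Plots whose sampled covariates make ω0 or ω1
    non-positive are resampled (with a warning giving the count), so the
    generating law is always a valid growth curve.
    """
    if not plots:
        raise ValueError("plots must be nonempty")
    rng = np.random.default_rng(cfg.seed + 1)
    resampled = 0
    valid_plots: list[PlotRecord] = []
    for plot in plots:
        current = plot
        for _ in range(100):
            w0, w1 = _plot_omegas(cfg, current)
            if w0 > 0 and w1 > 0:
                break
            resampled += 1
            current = _sample_plot(cfg, rng, plot.plot_id)
        else:
            raise RuntimeError(f"could not sample valid growth parameters "
                               f"for plot {plot.plot_id}")
        valid_plots.append(current)
    if resampled:
        warnings.warn(f"resampled {resampled} plot(s) with non-positive "
                      f"growth parameters", stacklevel=2)

    lo_age, hi_age = cfg.first_age_range
    observations: list[TreeObservation] = []
    coeffs = cfg.coefficients
    for plot in valid_plots:
        plot_age = int(rng.integers(lo_age, hi_age + 1))
        X = np.array([[plot.covariate(v) for v in coeffs.variable_names]])
        for tree in range(cfg.trees_per_plot):
            if cfg.age_structure == "even":
                jitter = int(rng.integers(-cfg.age_jitter, cfg.age_jitter + 1))
                first_age = int(np.clip(plot_age + jitter, lo_age, hi_age))
            else:
                first_age = int(rng.integers(lo_age, hi_age + 1))
            for s in range(cfg.surveys_per_tree):
                age = first_age + s * cfg.survey_interval
                mean = float(rp_predict_matrix(coeffs, X,
                                               np.array([float(age)]))[0])
                value = mean + (rng.normal(0.0, cfg.noise_sd)
                                if cfg.noise_sd > 0 else 0.0)
                observations.append(TreeObservation(
                    plot_id=plot.plot_id, tree_id=f"T{tree + 1:03d}",
                    survey_year=cfg.base_year + s * cfg.survey_interval,
                    T=age, response_kind=cfg.response_kind,
                    response_value=max(value, cfg.response_floor)))
    return Dataset(observations, {p.plot_id: p for p in valid_plots},
                   cfg.response_kind)


def generate_dataset(cfg: GeneratorConfig) -> Dataset:
    """Convenience wrapper: plots then observations from one config."""
    return generate_observations(generate_plots(cfg), cfg)


def inject_outliers(ds: Dataset, rate: float, magnitude: float,
                    seed: int = 0) -> tuple[Dataset, list[tuple]]:
    """Corrupt a fraction of observations by ±magnitude plot standard
    deviations — a controlled test bed for the Pauta filter.

    ``magnitude`` must exceed 3 (otherwise the shift is not an outlier under
    the 3σ rule by construction).  Returns the corrupted dataset and the
    (plot_id, tree_id, survey_year) keys of the injected observations.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if magnitude <= 3:
        raise ValueError("magnitude must exceed 3 plot standard deviations")
    rng = np.random.default_rng(seed)
    n_inject = int(round(rate * len(ds)))
    if n_inject == 0:
        return ds, []
    by_plot: dict[str, list[float]] = {}
    for o in ds.observations:
        by_plot.setdefault(o.plot_id, []).append(o.response_value)
    plot_sd = {p: float(np.std(v, ddof=1)) if len(v) > 1 else 1.0
               for p, v in by_plot.items()}
    chosen = set(rng.choice(len(ds), size=n_inject, replace=False).tolist())
    new_obs: list[TreeObservation] = []
    injected: list[tuple] = []
    for i, o in enumerate(ds.observations):
        if i in chosen:
            shift = magnitude * max(plot_sd[o.plot_id], 1e-6)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            value = max(o.response_value + sign * shift, 1e-3)
            new_obs.append(TreeObservation(o.plot_id, o.tree_id,
                                           o.survey_year, o.T,
                                           o.response_kind, value))
            injected.append((o.plot_id, o.tree_id, o.survey_year))
        else:
            new_obs.append(o)
    return Dataset(new_obs, dict(ds.plots), ds.response_kind), injected
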
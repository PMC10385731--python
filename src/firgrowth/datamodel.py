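"""Domain types and I/O for continuous-forest-inventory (CFI) style tree data.

The unit of observation is one tree at one survey: an age ``T`` (years) and a
single response, either diameter at breast height (DBH, cm) or total height
(H, m).  Plot-level context — stand density ``N``, site factors and annual
climate variables — is stored once per plot and joined onto observations when
a modelling matrix is needed.

Site factors follow the coded scheme used in Fujian CFI field records:
landform (DM), slope aspect (PX), slope position (PW) and soil name (TRMC)
are small integer codes; elevation (HB, m), slope gradient (PD, degrees) and
soil thickness (TRHD, mm as recorded) are continuous.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Legal codes for the non-quantified site factors.
DM_CODES = frozenset({3, 4, 5})        # middle mountains / low mountains / hills
PX_CODES = frozenset(range(1, 9))      # eight compass aspects, N=1 .. NW=8
PW_CODES = frozenset(range(1, 7))      # ridge .. flat
TRMC_CODES = frozenset({12, 13})       # red soil / lateritic soil

#: Climate keys every dataset must carry (13 more may be present).
REQUIRED_CLIMATE = ("DD18", "MAP", "Eref", "MAT", "MCMT")

RESPONSE_KINDS = ("DBH", "H")

SITE_COLUMNS = ("HB", "PD", "TRHD", "DM", "PX", "PW", "TRMC")
ID_COLUMNS = ("plot_id", "tree_id", "survey_year")


class SchemaError(ValueError):
    """A mandatory column is missing or the header does not match the schema."""


class ValidationError(ValueError):
    """Row-level values violate the coding scheme or an invariant."""


@dataclass(frozen=True)
class SiteFactors:
    """Site description of one plot (Fujian CFI coding)."""

    HB: float          # elevation, m
    PD: float          # slope gradient, degrees
    TRHD: float        # soil thickness, mm as recorded
    DM: int            # landform code
    PX: int            # slope-aspect code
    PW: int            # slope-position code
    TRMC: int          # soil-name code

    def __post_init__(self) -> None:
        if self.HB < 0:
            raise ValidationError(f"HB must be >= 0, got {self.HB}")
        if not 0 <= self.PD <= 90:
            raise ValidationError(f"PD must be in [0, 90], got {self.PD}")
        if self.TRHD <= 0:
            raise ValidationError(f"TRHD must be > 0, got {self.TRHD}")
        for name, codes in (("DM", DM_CODES), ("PX", PX_CODES),
                            ("PW", PW_CODES), ("TRMC", TRMC_CODES)):
            value = getattr(self, name)
            if value not in codes:
                raise ValidationError(
                    f"{name}={value} outside legal codes {sorted(codes)}")


@dataclass(frozen=True)
class ClimateFactors:
    """Annual climate variables for one plot.

    ``values`` maps variable name to value; the five required keys are
    degree-days above 18 degC (DD18), mean annual precipitation (MAP, mm),
    Hargreaves reference evaporation (Eref, mm), mean annual temperature
    (MAT, degC) and mean coldest-month temperature (MCMT, degC).
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [k for k in REQUIRED_CLIMATE if k not in self.values]
        if missing:
            raise ValidationError(f"missing required climate keys: {missing}")
        v = self.values
        if v["DD18"] < 0:
            raise ValidationError("DD18 must be >= 0")
        if v["MAP"] <= 0 or v["Eref"] <= 0:
            raise ValidationError("MAP and Eref must be > 0")

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])

    def names(self) -> tuple[str, ...]:
        return tuple(self.values.keys())


@dataclass(frozen=True)
class PlotRecord:
    """One inventory plot: competition (density N), site and climate."""

    plot_id: str
    N: int                     # stems per plot (~667 m^2)
    site: SiteFactors
    climate: ClimateFactors

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValidationError(f"N must be > 0, got {self.N}")

    def covariate(self, name: str) -> float:
        """Look up any plot-level covariate (N, a site factor, or climate)."""
        if name == "N":
            return float(self.N)
        if name in SITE_COLUMNS:
            return float(getattr(self.site, name))
        return self.climate[name]


@dataclass(frozen=True)
class TreeObservation:
    """One tree at one survey."""

    plot_id: str
    tree_id: str
    survey_year: int
    T: int                     # age, years
    response_kind: str         # "DBH" or "H"
    response_value: float      # cm or m

    def __post_init__(self) -> None:
        if self.response_kind not in RESPONSE_KINDS:
            raise ValidationError(f"response_kind must be one of {RESPONSE_KINDS}")
        if self.response_value <= 0:
            raise ValidationError("response_value must be > 0")
        if self.T < 1:
            raise ValidationError("T must be >= 1")


@dataclass
class Dataset:
    """A homogeneous collection of observations plus their plots."""

    observations: list[TreeObservation]
    plots: dict[str, PlotRecord]
    response_kind: str

    def __post_init__(self) -> None:
        if self.response_kind not in RESPONSE_KINDS:
            raise ValidationError(f"response_kind must be one of {RESPONSE_KINDS}")
        kinds = {o.response_kind for o in self.observations}
        if kinds - {self.response_kind}:
            raise ValidationError(
                f"observations carry response kinds {sorted(kinds)}, "
                f"dataset declares {self.response_kind}")
        unresolved = {o.plot_id for o in self.observations} - set(self.plots)
        if unresolved:
            raise ValidationError(f"observations reference unknown plots: "
                                  f"{sorted(unresolved)[:5]}")
        keys = [(o.plot_id, o.tree_id, o.survey_year) for o in self.observations]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (plot_id, tree_id, survey_year) keys")

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def climate_names(self) -> tuple[str, ...]:
        if not self.plots:
            return tuple(REQUIRED_CLIMATE)
        first = next(iter(self.plots.values()))
        return first.climate.names()

    def subset(self, observations: Iterable[TreeObservation]) -> "Dataset":
        obs = list(observations)
        plot_ids = {o.plot_id for o in obs}
        return Dataset(obs, {p: r for p, r in self.plots.items() if p in plot_ids},
                       self.response_kind)

    def to_frame(self) -> pd.DataFrame:
        """One row per observation with plot covariates joined on."""
        rows = []
        for o in self.observations:
            plot = self.plots[o.plot_id]
            row = {"plot_id": o.plot_id, "tree_id": o.tree_id,
                   "survey_year": o.survey_year, "T": o.T,
                   self.response_kind: o.response_value, "N": plot.N}
            for c in SITE_COLUMNS:
                row[c] = getattr(plot.site, c)
            row.update(plot.climate.values)
            rows.append(row)
        columns = list(ID_COLUMNS) + ["T", self.response_kind, "N"] \
            + list(SITE_COLUMNS) + list(self.climate_names)
        return pd.DataFrame(rows, columns=columns)

    def covariate_matrix(self, names: list[str]) -> np.ndarray:
        """Plot-level covariates per observation, column order = ``names``."""
        out = np.empty((len(self.observations), len(names)))
        for i, o in enumerate(self.observations):
            plot = self.plots[o.plot_id]
            for j, name in enumerate(names):
                out[i, j] = plot.covariate(name)
        return out

    @property
    def ages(self) -> np.ndarray:
        return np.array([o.T for o in self.observations], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.array([o.response_value for o in self.observations])


@dataclass(frozen=True)
class CovariateVector:
    """Ordered numeric values for a named variable list."""

    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValidationError("names and values differ in length")
        if any(v is None or not np.isfinite(v) for v in self.values):
            raise ValidationError("covariate values must be finite")

    @classmethod
    def from_plot(cls, plot: PlotRecord, names: Iterable[str]) -> "CovariateVector":
        names = tuple(names)
        return cls(names, tuple(plot.covariate(n) for n in names))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _detect_response_column(columns: Iterable[str]) -> str:
    present = [k for k in RESPONSE_KINDS if k in columns]
    if len(present) != 1:
        raise SchemaError(
            f"expected exactly one response column of {RESPONSE_KINDS}, "
            f"found {present}")
    return present[0]


def read_dataset(path, response_kind: str | None = None) -> Dataset:
    """Read the standard CSV schema into a :class:`Dataset`.

    Columns: plot_id, tree_id, survey_year, T, DBH-or-H, N, the seven site
    factors, then climate variables by name.  Codes are validated against the
    CFI enumerations; offending rows are reported by (1-based) data row
    number.
    """
    df = pd.read_csv(path)
    response_col = _detect_response_column(df.columns)
    if response_kind is not None and response_col != response_kind:
        raise SchemaError(
            f"file carries response column {response_col!r}, "
            f"expected {response_kind!r}")
    mandatory = list(ID_COLUMNS) + ["T", response_col, "N"] + list(SITE_COLUMNS)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    missing_clim = [c for c in REQUIRED_CLIMATE if c not in df.columns]
    if missing_clim:
        raise SchemaError(f"missing required climate columns: {missing_clim}")

    climate_cols = [c for c in df.columns if c not in mandatory]
    bad_rows: list[tuple[int, str]] = []
    for name, codes in (("DM", DM_CODES), ("PX", PX_CODES),
                        ("PW", PW_CODES), ("TRMC", TRMC_CODES)):
        bad = ~df[name].isin(sorted(codes))
        for idx in df.index[bad]:
            bad_rows.append((int(idx) + 1, f"{name}={df.at[idx, name]}"))
    if bad_rows:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in bad_rows[:10])
        raise ValidationError(f"illegal site-factor codes ({detail})")

    plots: dict[str, PlotRecord] = {}
    observations: list[TreeObservation] = []
    for _, row in df.iterrows():
        pid = str(row["plot_id"])
        if pid not in plots:
            site = SiteFactors(HB=float(row["HB"]), PD=float(row["PD"]),
                               TRHD=float(row["TRHD"]), DM=int(row["DM"]),
                               PX=int(row["PX"]), PW=int(row["PW"]),
                               TRMC=int(row["TRMC"]))
            climate = ClimateFactors(
                {c: float(row[c]) for c in climate_cols})
            plots[pid] = PlotRecord(plot_id=pid, N=int(row["N"]),
                                    site=site, climate=climate)
        observations.append(TreeObservation(
            plot_id=pid, tree_id=str(row["tree_id"]),
            survey_year=int(row["survey_year"]), T=int(row["T"]),
            response_kind=response_col,
            response_value=float(row[response_col])))
    return Dataset(observations, plots, response_col)


def write_dataset(ds: Dataset, path) -> None:
    """Write ``ds`` in the standard CSV schema (stable column order)."""
    df = ds.to_frame()
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Cleaning and splitting
# ---------------------------------------------------------------------------

def pauta_filter(ds: Dataset) -> tuple[Dataset, list[TreeObservation]]:
    """Pauta-criterion (3 sigma) outlier removal, plot by plot.

    Within each plot the response mean and sample standard deviation are
    computed once, on the original values; observations deviating by more
    than three standard deviations are removed in a single pass.  Plots with
    fewer than three observations pass through unfiltered (the sample sd is
    too unstable to trust there).
    """
    if not ds.observations:
        raise ValidationError("pauta_filter needs at least one observation")
    kept: list[TreeObservation] = []
    removed: list[TreeObservation] = []
    by_plot: dict[str, list[TreeObservation]] = {}
    for o in ds.observations:
        by_plot.setdefault(o.plot_id, []).append(o)
    for obs in by_plot.values():
        values = np.array([o.response_value for o in obs])
        if len(obs) < 3:
            kept.extend(obs)
            continue
        mean = values.mean()
        sd = values.std(ddof=1)
        for o, y in zip(obs, values):
            if sd > 0 and abs(y - mean) > 3 * sd:
                removed.append(o)
            else:
                kept.append(o)
    return ds.subset(kept), removed


def split_train_test(ds: Dataset, fraction: float = 0.8,
                     seed: int = 0, by_plot: bool = False,
                     ) -> tuple[Dataset, Dataset]:
    """Random train/test partition of observations (80/20 by default).

    With ``by_plot=True`` whole plots are assigned to one side, which avoids
    plot-level leakage but is off by default to match the conventional
    observation-level split.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if len(ds) < 2:
        raise ValidationError("need at least 2 observations to split")
    rng = np.random.default_rng(seed)
    if by_plot:
        plot_ids = sorted(ds.plots)
        rng.shuffle(plot_ids)
        n_train = int(round(fraction * len(plot_ids)))
        train_plots = set(plot_ids[:n_train])
        train = [o for o in ds.observations if o.plot_id in train_plots]
        test = [o for o in ds.observations if o.plot_id not in train_plots]
    else:
        index = rng.permutation(len(ds))
        n_train = int(round(fraction * len(ds)))
        train = [ds.observations[i] for i in sorted(index[:n_train])]
        test = [ds.observations[i] for i in sorted(index[n_train:])]
    return ds.subset(train), ds.subset(test)
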
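"""Shared fixtures: hand-built miniature datasets and generated inventories."""

from __future__ import annotations

import numpy as np
import pytest

from firgrowth.datamodel import (ClimateFactors, Dataset, PlotRecord,
                                 SiteFactors, TreeObservation)
from firgrowth.synthetic import GeneratorConfig, generate_dataset

BASE_CLIMATE = {"DD18": 1500.0, "MAP": 1700.0, "Eref": 850.0,
                "MAT": 19.0, "MCMT": 9.0}


def make_plot(plot_id: str, N: int = 121, HB: float = 423.0, PD: float = 9.0,
              TRHD: float = 98.0, DM: int = 4, PX: int = 2, PW: int = 3,
              TRMC: int = 12, **climate) -> PlotRecord:
    clim = dict(BASE_CLIMATE)
    clim.update(climate)
    return PlotRecord(plot_id=plot_id, N=N,
                      site=SiteFactors(HB=HB, PD=PD, TRHD=TRHD, DM=DM,
                                       PX=PX, PW=PW, TRMC=TRMC),
                      climate=ClimateFactors(clim))


def make_dataset(plot_values: dict[str, list[float]],
                 response_kind: str = "DBH", ages=None) -> Dataset:
    """One observation per listed response value, grouped by plot."""
    plots = {}
    observations = []
    for pid, values in plot_values.items():
        plots[pid] = make_plot(pid)
        for i, v in enumerate(values):
            observations.append(TreeObservation(
                plot_id=pid, tree_id=f"t{i}", survey_year=2000 + i,
                T=int(ages[i]) if ages is not None else 10 + i,
                response_kind=response_kind, response_value=float(v)))
    return Dataset(observations, plots, response_kind)


@pytest.fixture(scope="session")
def small_inventory() -> Dataset:
    """A modest simulated inventory for generic unit tests (720 rows)."""
    cfg = GeneratorConfig(seed=7, n_plots=120, trees_per_plot=3,
                          surveys_per_tree=2)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_inventory() -> Dataset:
    """The generator's default study conditions (shared; generated once)."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
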
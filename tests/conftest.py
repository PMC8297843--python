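"""Shared fixtures: a small synthetic landscape and hand-built tables."""

import numpy as np
import pandas as pd
import pytest

from habsel import synthetic
from habsel.grids import Grid, LandscapeStack
from habsel.preprocess import UsedAvailableTable


@pytest.fixture(scope="session")
def landscape_and_roads():
    """One deterministic 6 x 6 km landscape shared across tests."""
    return synthetic.gen_landscape(extent_m=(6000.0, 6000.0), seed=42,
                                   n_roads=10)


@pytest.fixture(scope="session")
def landscape(landscape_and_roads):
    return landscape_and_roads[0]


@pytest.fixture(scope="session")
def roads(landscape_and_roads):
    return landscape_and_roads[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_table(df: pd.DataFrame, scaling=None, reference_level="conifer",
               cover_levels=None) -> UsedAvailableTable:
    """UsedAvailableTable around a hand-built frame."""
    for col in ("animal_id", "pack_id", "study_area"):
        if col not in df:
            df = df.assign(**{col: "t"})
    return UsedAvailableTable(df=df, scaling=scaling or {},
                              reference_level=reference_level,
                              cover_levels=cover_levels or [])


@pytest.fixture()
def binary_2x2_table():
    """40 used / 400 available at x=0 and 60 used / 100 available at x=1.

    Closed-form logistic solution: intercept log(40/400), slope
    log((60/100)/(40/400)) = log 6.
    """
    response = np.concatenate([np.ones(40), np.zeros(400),
                               np.ones(60), np.zeros(100)])
    x = np.concatenate([np.zeros(440), np.ones(160)])
    return make_table(pd.DataFrame({"response": response, "x": x}))
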
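import numpy as np
import pandas as pd
import pytest

from gwrflow.gwr import KernelSpec, fit_gwr
from gwrflow.preprocess import DEFAULT_COVARIATES, build_model_table
from gwrflow.synthetic import CityConfig, generate_city


@pytest.fixture(scope="session")
def default_city():
    """The study-condition synthetic city: 174 neighbourhoods, default calibration."""
    return generate_city(CityConfig(seed=7))


@pytest.fixture(scope="session")
def model_table(default_city):
    table, _ = build_model_table(default_city.table)
    return table


@pytest.fixture(scope="session")
def obesity_fit(model_table):
    return fit_gwr(model_table, "normalized_obese", DEFAULT_COVARIATES, KernelSpec("adaptive", 50))


@pytest.fixture(scope="session")
def overweight_fit(model_table):
    return fit_gwr(model_table, "normalized_overweight", DEFAULT_COVARIATES, KernelSpec("adaptive", 50))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_regression_table(rng, n=30, k=3, coef=None, noise=1.0):
    """Small random regression problem with known construction."""
    X = rng.normal(size=(n, k))
    coef = np.arange(1, k + 1) if coef is None else np.asarray(coef)
    y = 0.5 + X @ coef + noise * rng.normal(size=n)
    cols = {f"x{j}": X[:, j] for j in range(k)}
    return pd.DataFrame(
        {
            "id": [f"S{i}" for i in range(n)],
            "u": rng.uniform(0, 1000, n),
            "v": rng.uniform(0, 1000, n),
            "y": y,
            **cols,
        }
    )
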
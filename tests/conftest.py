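import numpy as np
import pytest

from bqrbmi.encoding import ContinuousSpec, CovariateSchema
from bqrbmi.gibbs import EncodedDataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240424)


@pytest.fixture(scope="session")
def simple_dataset():
    """n=200, p=3: intercept + two continuous covariates, gaussian noise."""
    rng = np.random.default_rng(7)
    n = 200
    x1 = rng.uniform(0, 3, n)
    x2 = rng.uniform(-1, 1, n)
    design = np.column_stack([np.ones(n), x1, x2])
    y = 2.0 + 0.8 * x1 - 0.5 * x2 + rng.standard_normal(n)
    return EncodedDataset(y, design, ["Intercept", "x1", "x2"])


@pytest.fixture(scope="session")
def locscale_schema():
    """Intercept + one continuous regressor on [0, 4], for location-scale truth."""
    return CovariateSchema(
        categorical_specs=(),
        continuous_specs=(ContinuousSpec("x", 0, 4, "uniform"),),
    )
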
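import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import crossmed as cm
from crossmed import popgen

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scenario1():
    return cm.ScenarioSpec.default(1)


@pytest.fixture(scope="session")
def scenario8():
    return cm.ScenarioSpec.default(8)


@pytest.fixture(scope="session")
def strata():
    return cm.default_strata()


@pytest.fixture(scope="session")
def small_population(scenario1):
    """A modest scenario-1 population used across estimation tests."""
    return cm.generate_population(12_000, spec=scenario1, rng_seed=42)


@pytest.fixture(scope="session")
def small_sample(small_population):
    design = cm.SamplingDesign.default(cm.SamplingMethod.COV_MED, 1_200)
    return cm.draw_sample(small_population, design, rng_seed=7)


@pytest.fixture()
def toy_sample():
    """A tiny handmade 'sample' with all required columns."""
    rng = np.random.default_rng(3)
    n = 400
    df = pd.DataFrame({
        c: rng.integers(0, 2, n) for c in popgen.COVARIATES
    })
    df["A"] = rng.integers(0, 2, n)
    df["M"] = rng.integers(0, 2, n)
    df["Y"] = rng.integers(0, 2, n)
    df["s_weight"] = rng.uniform(0.5, 3.0, n)
    return df
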
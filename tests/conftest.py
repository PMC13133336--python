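import numpy as np
import pytest

import pacteval as pe


@pytest.fixture(scope="session")
def small_scenario() -> pe.ScenarioTruth:
    """A compact known-effect scenario reused across matching tests.

    30 km landscape, 2.5 kha project, ~2%/yr hazard halved inside the
    project after 2011, simulated 1999-2021.
    """
    return pe.make_scenario(
        grid=pe.GridSpec(300, 300, pixel_size=100.0),
        project_shape=(50, 50),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_units(small_scenario):
    """Project unit table and candidate pool for the small scenario."""
    from pacteval.matching import candidate_pool, epoch_cover_rasters, sample_units, unit_table

    stack = small_scenario.factual
    cov = epoch_cover_rasters(stack, small_scenario.t0)
    rows, cols = sample_units(small_scenario.project_polygon, stack.grid)
    proj = unit_table(stack, rows, cols, small_scenario.t0, cover_rasters=cov)
    pool = candidate_pool(
        stack,
        small_scenario.project_polygon,
        proj,
        small_scenario.t0,
        pool_density=0.25,
        cover_rasters=cov,
    )
    return proj, pool


def random_unit_frame(rng: np.random.Generator, n: int, n_classes: int = 2):
    """Synthetic sample-unit table with well-conditioned continuous covariates."""
    import pandas as pd

    from pacteval.matching import CATEGORICAL_COVARIATES, CONTINUOUS_COVARIATES

    data = {
        "row": rng.integers(0, 500, n),
        "col": rng.integers(0, 500, n),
    }
    for name in CONTINUOUS_COVARIATES:
        data[name] = rng.normal(size=n)
    for name in CATEGORICAL_COVARIATES:
        data[name] = rng.integers(0, n_classes, n)
    return pd.DataFrame(data)
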
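import numpy as np
import pytest

import popgse as pg


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject cohort with a clearly planted class signal."""
    return pg.generate_cohort(
        pg.SimulationParams(n_patients=30, n_controls=30, r=10, seed=7)
    )


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return pg.vectorize_rsfc(small_cohort)


@pytest.fixture(scope="session")
def rsfc_graph(small_cohort, small_features):
    return pg.build_population_graph(
        small_features, small_cohort, pg.GraphConfig(use_rsfc=True)
    )


@pytest.fixture(scope="session")
def rsfc_basis(rsfc_graph):
    return pg.eigendecompose(pg.combinatorial_laplacian(rsfc_graph))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
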
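import numpy as np
import pytest

from mitoswitch import PopulationSpec, default_dose_grid, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def population():
    """The fitted assay population: log-normal CycB, 64 quadrature nodes."""
    return PopulationSpec(median=8.18, sd=4.31, n_quantiles=64)


@pytest.fixture(scope="session")
def dose_grid():
    """Zero + 25 log-spaced doses in [0.01, 2] μM (the assay's default)."""
    return default_dose_grid()


@pytest.fixture(scope="session")
def refined_dose_grid():
    """Default grid refined below 200 nM for the low-threshold conditions."""
    return np.unique(np.concatenate([default_dose_grid(),
                                     np.linspace(0.02, 0.2, 19)]))


def random_valid_states(params, n, seed):
    """Sample states uniformly from the invariant box (conservation-aware)."""
    rng = np.random.default_rng(seed)
    tot = np.array([params.SubTot, params.CycBTot, params.PP1Tot,
                    params.ENSATot, params.GwlTot, params.B55Tot,
                    1.0, 1.0, 1.0, 1.0])
    y = rng.uniform(0.0, 1.0, (n, 10)) * tot
    y[:, 7] *= 1.0 - y[:, 6]
    y[:, 9] *= 1.0 - y[:, 8]
    # keep the pENSA:B55 complex inside [0, pENSATot]
    y[:, 5] = np.maximum(y[:, 5], params.B55Tot - y[:, 3])
    return y
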
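import warnings

import pytest

import twodom as td


@pytest.fixture(scope="session")
def constants():
    return td.SystemConstants()


@pytest.fixture(scope="session")
def wt_params():
    # wild-type posterior medians under the default prior
    return td.ModelParams(eps_D=0.0, eps_L=6.61, gamma=5.29)


@pytest.fixture(scope="session")
def panel():
    return td.panel_fixture()


@pytest.fixture(scope="session")
def wt_dataset(wt_params, constants):
    return td.simulate_dataset(wt_params, constants, seed=1, mutant_id="WT")


@pytest.fixture(scope="session")
def wt_fit(wt_dataset, constants):
    """One wild-type fit conditioned on the generative eps_D, shared
    across tests that only need a converged posterior."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return td.fit_posterior(wt_dataset, 0.0, constants, seed=101)
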
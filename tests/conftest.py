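import pytest

import pregpbpk as pk


@pytest.fixture(scope="session")
def configs():
    return pk.load_config()


@pytest.fixture(scope="session")
def drug(configs):
    return configs[0]


@pytest.fixture(scope="session")
def physiology(configs):
    return configs[1]


@pytest.fixture(scope="session")
def coeffs(configs):
    return configs[2]


@pytest.fixture(scope="session")
def regimen_200():
    """The calibration-study regimen: 200 mg daily for 30 days."""
    return pk.Regimen(dose_mg=200.0, interval_h=24.0, n_doses=30)


@pytest.fixture(scope="session")
def baseline_sim(configs, regimen_200):
    """Nonpregnant steady-state simulation with washout, shared across tests."""
    drug, phys, coeffs = configs
    params = pk.build_model_params(drug, phys, coeffs, 0.0)
    return pk.simulate(params, regimen_200, washout_h=72.0)


@pytest.fixture(scope="session")
def baseline_nca(baseline_sim):
    return pk.nca(baseline_sim)


@pytest.fixture(scope="session")
def ga34_sim(configs, regimen_200):
    drug, phys, coeffs = configs
    params = pk.build_model_params(drug, phys, coeffs, 34.0)
    return pk.simulate(params, regimen_200, washout_h=72.0)
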
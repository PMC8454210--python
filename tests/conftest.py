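import pytest

from leafopt import (PhysioConstants, TransectScenario, generate_sites,
                     generate_traits)


@pytest.fixture(scope="session")
def constants() -> PhysioConstants:
    return PhysioConstants()


@pytest.fixture(scope="session")
def scenario() -> TransectScenario:
    return TransectScenario(seed=42)


@pytest.fixture(scope="session")
def sites(scenario, constants):
    return generate_sites(scenario, constants)


@pytest.fixture(scope="session")
def traits(sites, scenario, constants):
    return generate_traits(sites, scenario, constants)


@pytest.fixture(scope="session")
def noiseless_scenario() -> TransectScenario:
    return TransectScenario(seed=7, sd_ln_ma=0.0, sd_ln_vcmax25=0.0,
                            sd_ln_chi=0.0, sd_ln_narea=0.0,
                            evergreen_fraction=0.0, n_fixer_fraction=0.0)
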
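import pytest
from hypothesis import settings

from flydpm import data

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from flydpm.engine import compile_network
from flydpm.synthdata import midgut_demo, oracle_fixtures


@pytest.fixture(scope="session")
def isc_net():
    return data.load_isc_network()


@pytest.fixture(scope="session")
def isc_compiled(isc_net):
    return compile_network(isc_net)


@pytest.fixture(scope="session")
def isc_fates():
    return data.load_isc_fates()


@pytest.fixture(scope="session")
def isc_normal_clamps():
    return data.load_isc_normal_clamps()


@pytest.fixture(scope="session")
def demo():
    return midgut_demo()


@pytest.fixture(scope="session")
def oracle_catalog():
    return oracle_fixtures()
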
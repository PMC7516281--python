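import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from sbolkit import fixtures  # noqa: E402


@pytest.fixture()
def autoreg_doc():
    return fixtures.build_autoregulatory_device()


@pytest.fixture()
def toggle_doc():
    return fixtures.build_toggle_switch()


@pytest.fixture()
def multicellular_doc():
    return fixtures.build_multicellular_system()


@pytest.fixture()
def nor_gate_doc():
    return fixtures.build_nor_gate()


@pytest.fixture()
def combinatorial_doc():
    return fixtures.build_combinatorial_template()


@pytest.fixture(params=sorted(fixtures.FIXTURE_BUILDERS))
def any_fixture_doc(request):
    return fixtures.FIXTURE_BUILDERS[request.param]()
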
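import pytest
from hypothesis import settings

from mirharmony import fixtures as fx

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from mirharmony.namespace_engine import build_namespace_from_release


@pytest.fixture(scope="session")
def toy3():
    """Hand-scripted two-release series: rename, deletion, scripted collision."""
    return fx.toy3()


@pytest.fixture(scope="session")
def toy3_index(toy3):
    return toy3[0]


@pytest.fixture(scope="session")
def toy3_events(toy3):
    return toy3[1]


@pytest.fixture(scope="session")
def ns_v1(toy3_index):
    return build_namespace_from_release(toy3_index.get("v1"), "syn")


@pytest.fixture(scope="session")
def ns_v2(toy3_index):
    return build_namespace_from_release(toy3_index.get("v2"), "syn")


@pytest.fixture(scope="session")
def platform_p1(toy3_index):
    """Consistent platform derived verbatim from toy3/v1: 3 probes + 1 control."""
    spec = fx.PlatformSpec("P1", "v1", n_probes=3, n_controls=1)
    platform, manifest = fx.derive_platform(toy3_index.get("v1"), spec, seed=1)
    assert manifest == []
    return platform


@pytest.fixture(scope="session")
def platform_p_err(toy3_index):
    """Platform with one injected name↔sequence mismatch, plus its manifest."""
    spec = fx.PlatformSpec("Perr", "v1", n_probes=3, n_injected_mismatches=1)
    return fx.derive_platform(toy3_index.get("v1"), spec, seed=1)
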
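import pytest
from hypothesis import HealthCheck, settings

from mitorearr import ancestral_order, load_heteroptera_catalog

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ancestral():
    return ancestral_order()


@pytest.fixture(scope="session")
def catalog():
    return load_heteroptera_catalog()


@pytest.fixture(scope="session")
def record_by_prefix(catalog):
    def find(prefix):
        for rec in catalog:
            if rec.taxon.startswith(prefix):
                return rec
        raise KeyError(prefix)
    return find
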
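import pytest
from hypothesis import HealthCheck, settings

from chipconcord.concordance import join_and_classify
from chipconcord.membership import build_position_index, check_batch
from chipconcord.simulate import REF_1000G, REF_HAPMAP, published_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_dataset():
    """The deterministic 415-SNP dataset shaped like the published audit."""
    return published_fixture()


@pytest.fixture(scope="session")
def fixture_calls(fixture_dataset):
    index = build_position_index(fixture_dataset.manifest)
    return check_batch(fixture_dataset.queries, index)


@pytest.fixture(scope="session")
def fixture_records(fixture_dataset, fixture_calls):
    """reference label -> classified per-SNP records, for both panels."""
    return {
        ref: join_and_classify(fixture_calls, fixture_dataset.claims[ref], ref)
        for ref in (REF_HAPMAP, REF_1000G)
    }
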
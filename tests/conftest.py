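import pytest

from trialscape import FixtureConfig, generate_annotations, generate_snapshot
from trialscape.curation import CurationStore
from trialscape.normalize import process_snapshot


def build_store(config: FixtureConfig) -> CurationStore:
    """Run the full offline pipeline for a fixture config into a memory store."""
    snapshot, _ = generate_snapshot(config)
    result = process_snapshot(snapshot)
    store = CurationStore()
    store.upsert_terms(result.conditions)
    store.upsert_terms(result.countries)
    store.upsert_records(result.records)
    for annotation in generate_annotations(snapshot, config):
        store.set_annotation(annotation)
    return store


@pytest.fixture
def fixture_config() -> FixtureConfig:
    return FixtureConfig(seed=11, n_records=200)


@pytest.fixture
def populated(fixture_config):
    snapshot, truth = generate_snapshot(fixture_config)
    store = build_store(fixture_config)
    yield store, truth, snapshot
    store.close()
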
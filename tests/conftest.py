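import pytest

from phagepipe.consensus import agreement_stats, merge_predictions
from phagepipe.synthetic_data import (
    DEFAULT_CALLERS,
    load_curation_cases,
    seao1_agreement_fixture,
)


@pytest.fixture(scope="session")
def agreement_consensus():
    """Merged consensus of the packaged five-caller agreement fixture."""
    preds = seao1_agreement_fixture()
    return merge_predictions(
        [p for plist in preds.values() for p in plist], DEFAULT_CALLERS
    )


@pytest.fixture(scope="session")
def agreement_statistics(agreement_consensus):
    return agreement_stats(agreement_consensus, DEFAULT_CALLERS)


@pytest.fixture(scope="session")
def curation_cases():
    return load_curation_cases()
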
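import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from aufkit import EcosystemConfig, sample_ecosystem, score_records, summarize_ecosystem


@pytest.fixture(scope="session")
def market_sample():
    """One 20,000-app ecosystem draw at the calibrated rates, scored."""
    records = sample_ecosystem(EcosystemConfig(seed=20260927))
    return score_records(records)


@pytest.fixture(scope="session")
def market_summary(market_sample):
    return summarize_ecosystem(market_sample)
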
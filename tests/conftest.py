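import pytest

from crowdsolve import (
    PoolSpec,
    default_item_bank,
    sample_pool,
    score_responses,
    screen_by_crt,
)


@pytest.fixture(scope="session")
def bank():
    return default_item_bank()


@pytest.fixture(scope="session")
def pool95(bank):
    """Default study-scale pool: 95 workers, default calibration, seed 0."""
    return sample_pool(PoolSpec(n_workers=95, items=bank, seed=0))


@pytest.fixture(scope="session")
def scores95(pool95, bank):
    return score_responses(pool95, bank)


@pytest.fixture(scope="session")
def screen95(scores95):
    return screen_by_crt(scores95, threshold=2)


@pytest.fixture(scope="session")
def pool10k(bank):
    """Large pool for calibration-recovery checks."""
    return sample_pool(PoolSpec(n_workers=10_000, items=bank, seed=0))


@pytest.fixture(scope="session")
def scores10k(pool10k, bank):
    return score_responses(pool10k, bank)
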
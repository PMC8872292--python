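import numpy as np
import pytest
from hypothesis import settings

from fedfpm.dataset import TransactionDataset
from fedfpm.synthetic_cohorts import simulate_cohort, study_like_profiles, toy_fixture

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def toy() -> TransactionDataset:
    return toy_fixture()


@pytest.fixture
def random_dataset_factory():
    """Small random transaction datasets for oracle cross-checks."""

    def make(rng: np.random.Generator, max_items: int = 8, max_n: int = 30,
             density: float = 0.4) -> TransactionDataset:
        k = int(rng.integers(2, max_items + 1))
        universe = tuple("ABCDEFGHIJKLMNOP"[:k])
        n = int(rng.integers(1, max_n + 1))
        transactions = [
            tuple(i for i in universe if rng.random() < density) for _ in range(n)
        ]
        return TransactionDataset("rand", universe, transactions)

    return make


@pytest.fixture(scope="session")
def study_profiles():
    return study_like_profiles(seed=2022)


@pytest.fixture(scope="session")
def study_data(study_profiles):
    """The five simulated study-like cohorts (pooled n = 11,034)."""
    return {p.agent_id: simulate_cohort(p) for p in study_profiles}
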
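import random

import pytest

from surveyarm import TransactionDB


@pytest.fixture(scope="session")
def table4_db() -> TransactionDB:
    """The 1000-student commuting/arrival database reconstructed from the
    printed contingency table: 150 bike+on-time, 750 bus+on-time,
    50 bike+tardy, 50 bus+tardy."""
    itemsets = (
        [{"Biking", "OnTime"}] * 150
        + [{"TakingBus", "OnTime"}] * 750
        + [{"Biking", "Tardy"}] * 50
        + [{"TakingBus", "Tardy"}] * 50
    )
    return TransactionDB.from_itemsets(itemsets)


@pytest.fixture
def random_db_factory():
    """Small random transaction databases for oracle-equivalence and
    property tests: up to `max_t` transactions over up to `max_items`
    single-letter items."""

    def make(seed: int, max_t: int = 30, max_items: int = 8) -> TransactionDB:
        rng = random.Random(seed)
        alphabet = [chr(ord("A") + i) for i in range(rng.randint(2, max_items))]
        n = rng.randint(1, max_t)
        itemsets = []
        for _ in range(n):
            size = rng.randint(1, len(alphabet))
            itemsets.append(set(rng.sample(alphabet, size)))
        return TransactionDB.from_itemsets(itemsets)

    return make
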
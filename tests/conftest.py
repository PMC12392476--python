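import pytest

from symmine import (
    Cohort,
    MiningConfig,
    TransactionSet,
    table2_fixture,
    to_transactions,
)

import pandas as pd


@pytest.fixture(scope="session")
def fixture_cohort() -> Cohort:
    return table2_fixture()


@pytest.fixture(scope="session")
def fixture_transactions(fixture_cohort) -> TransactionSet:
    return to_transactions(fixture_cohort)


@pytest.fixture
def toy_transactions() -> TransactionSet:
    """Six hand-countable transactions over items A, B, D."""
    raw = [{"A", "B", "D"}, {"A", "B", "D"}, {"A", "D"}, {"B"}, {"D"}, {"A", "B", "D"}]
    trans = tuple(frozenset(t) for t in raw)
    return TransactionSet(trans, frozenset().union(*trans))


@pytest.fixture
def toy_config() -> MiningConfig:
    return MiningConfig(min_support=0.3, min_confidence=0.6, target="D")


def make_cohort(rows: dict[str, list[int]], outcome: str = "Diabetes",
                numeric: tuple[str, ...] = ()) -> Cohort:
    return Cohort(pd.DataFrame(rows), outcome, numeric)
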
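import pandas as pd
import pytest

from jemforge import synthetic_uk_jem, synthetic_uk_workforce, uk_jobholder_crosstab_2020
from jemforge.core import RATING_COLUMNS


@pytest.fixture(scope="session")
def uk_jem():
    return synthetic_uk_jem()


@pytest.fixture(scope="session")
def uk_workforce(uk_jem):
    return synthetic_uk_workforce(uk_jem)


@pytest.fixture(scope="session")
def uk_crosstab():
    return uk_jobholder_crosstab_2020()


def make_ratings(rows):
    """Build a ratings table from (rater_id, code4, round, L, F, I) tuples;
    None marks a missing rating."""
    df = pd.DataFrame(rows, columns=list(RATING_COLUMNS))
    df["code4"] = df["code4"].astype(str)
    for axis in ("likelihood", "frequency", "intensity"):
        df[axis] = df[axis].astype("Int64")
    return df


@pytest.fixture
def ratings_factory():
    return make_ratings
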
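import datetime as dt

import numpy as np
import pytest

from mselink import ContingencyTable, RawRecord


@pytest.fixture
def independence_table() -> ContingencyTable:
    """Cells exactly proportional to an independence pattern (odds 2 per
    list): the no-interaction model fits it perfectly with m_000 = 1."""
    return ContingencyTable.from_counts(
        {"111": 8, "110": 4, "101": 4, "011": 4, "100": 2, "010": 2, "001": 2}
    )


@pytest.fixture
def moderate_table() -> ContingencyTable:
    """A well-behaved all-positive table of realistic size."""
    return ContingencyTable.from_counts(
        {"111": 25, "110": 17, "101": 17, "011": 11, "100": 11, "010": 7, "001": 7}
    )


def random_positive_tables(n_tables: int, seed: int, low: int = 1, high: int = 31):
    """Random small tables with strictly positive cells."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_tables):
        cells = rng.integers(low, high, size=7)
        out.append(
            ContingencyTable.from_counts(
                {
                    "111": cells[0],
                    "110": cells[1],
                    "101": cells[2],
                    "011": cells[3],
                    "100": cells[4],
                    "010": cells[5],
                    "001": cells[6],
                }
            )
        )
    return out


def make_record(**kwargs) -> RawRecord:
    defaults = dict(
        source_id="A",
        name="Test Person",
        gender="male",
        event_date=dt.date(2019, 1, 15),
        place="Khartoum",
        cause="gunshot",
        gunshot_site="chest",
        record_kind="death",
    )
    defaults.update(kwargs)
    return RawRecord(**defaults)
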
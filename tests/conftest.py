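import numpy as np
import pandas as pd
import pytest

from elevshift.config import AnalysisConfig


@pytest.fixture
def cfg():
    return AnalysisConfig()


def make_resurvey_frame(rows):
    """Build a resurvey DataFrame from (partial) row dicts with sane defaults."""
    defaults = dict(
        site_id="S", species_id="A", year_initial=1995, doy_initial=150,
        year_second=2018, doy_second=160, size_initial=10, survived=1,
        habitat_altered="no", elevation_m=1000.0, habitat_pref="forest",
    )
    out = []
    for i, r in enumerate(rows):
        d = {**defaults, "site_id": f"S{i}", **r}
        out.append(d)
    return pd.DataFrame(out)


@pytest.fixture
def resurvey_fixture_10():
    """10 engineered records: exactly one violates each filtering rule.

    Row 0 breaks the 30-day phenology window, row 1 belongs to a species
    seen only once initially (rarity), row 2 was revisited after 4 years.
    """
    rows = [
        {"doy_initial": 150, "doy_second": 181},             # phenology: 31-day gap
        {"species_id": "RARE"},                               # rarity: single record
        {"year_initial": 2014, "year_second": 2018},          # elapsed: 4 years
    ] + [{} for _ in range(7)]
    return make_resurvey_frame(rows)
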
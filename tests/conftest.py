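import numpy as np
import pandas as pd
import pytest

from utcidlnm.exposure import DailyExposureSeries
from utcidlnm.synthetic import (
    ClimateConfig,
    CohortConfig,
    NullSurface,
    generate_cohort,
    generate_daily_utci,
)


@pytest.fixture(scope="session")
def small_climate():
    """A small deterministic climate panel covering 1999-2016."""
    return generate_daily_utci(ClimateConfig(n_locations=3, seed=11))


@pytest.fixture(scope="session")
def small_cohort(small_climate):
    """2,000 pregnancies under the null surface (both outcomes present)."""
    conf = CohortConfig(n_pregnancies=2000, seed=12)
    return generate_cohort(
        conf,
        small_climate,
        {"gestational_hypertension": NullSurface(), "preeclampsia": NullSurface()},
    )


@pytest.fixture()
def constant_series():
    def make(value=14.0, start="1999-01-01", n_days=900, location_id="locX"):
        return DailyExposureSeries(
            location_id=location_id,
            start_date=np.datetime64(start),
            values=np.full(n_days, float(value)),
        )

    return make


def make_cohort_frame(rows):
    """Build a minimal cohort DataFrame from dicts with defaults filled."""
    defaults = {
        "location_id": "locX",
        "gestational_length": 40,
        "outcome": "none",
        "diagnosis_week": np.nan,
    }
    recs = []
    for i, r in enumerate(rows):
        d = dict(defaults)
        d["id"] = f"s{i}"
        d.update(r)
        recs.append(d)
    df = pd.DataFrame(recs)
    df["conception_date"] = pd.to_datetime(df["conception_date"])
    return df
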
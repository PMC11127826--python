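import datetime as dt

import numpy as np
import pytest

from somamat import (
    GrowthReferenceTable,
    Measurement,
    PlayerRecord,
    synthetic_default_reference,
)


@pytest.fixture(scope="session")
def toy_ref():
    """4-row toy reference: {15:(95,2), 16:(97,1.5), 17:(99,1), 18:(100,0.5)}."""
    return GrowthReferenceTable(
        age_grid=np.array([15.0, 16.0, 17.0, 18.0]),
        mean_pah=np.array([95.0, 97.0, 99.0, 100.0]),
        sd_pah=np.array([2.0, 1.5, 1.0, 0.5]),
        provenance_label="toy",
    )


@pytest.fixture(scope="session")
def default_ref():
    return synthetic_default_reference()


def make_player(
    pid="p1",
    baseline_height=176.0,
    adult_height=183.0,
    birth_date=dt.date(2000, 1, 1),
    baseline_date=dt.date(2016, 3, 15),
    n_semesters=6,
    recovered=None,
    **flags,
):
    """A simple player with linear growth between baseline and adult height."""
    measurements = []
    for k in range(n_semesters):
        h = baseline_height + (adult_height - baseline_height) * k / 5.0
        measurements.append(
            Measurement(
                semester=k + 1,
                measurement_date=baseline_date + dt.timedelta(days=round(182.625 * k)),
                height_cm=h,
                weight_kg=70.0,
            )
        )
    return PlayerRecord(
        player_id=pid,
        measurements=measurements,
        birth_date=birth_date,
        region="R01",
        year_of_collection=2016,
        recovered_adult_height=recovered,
        **flags,
    )
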
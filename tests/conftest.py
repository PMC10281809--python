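import datetime as dt

import numpy as np
import pandas as pd
import pytest

from reefspawn.synthetic import (
    AgeingErrorModel,
    GrowthModel,
    SpawningRegime,
    realize_fish,
    sample_hatch_dates,
)


@pytest.fixture(scope="session")
def noiseless_models():
    """Growth/ageing models with every noise source switched off and an
    integer mean PLD, so back-calculation can be exact."""
    growth = GrowthModel(length_noise_sd_mm=0.0)
    error = AgeingErrorModel(count_cv=0.0, pld_mean_days=28.0, pld_sd_days=0.0)
    return growth, error


@pytest.fixture(scope="session")
def bimodal_regime():
    """Two spawning pulses ~100 days apart in one austral year."""
    return SpawningRegime(
        components=[
            (dt.date(2020, 11, 1), 12.0, 1.0),
            (dt.date(2021, 2, 9), 12.0, 1.0),
        ],
        background_rate=0.0,
        date_range=(dt.date(2020, 7, 1), dt.date(2021, 6, 30)),
    )


@pytest.fixture(scope="session")
def small_fish_table(bimodal_regime, noiseless_models):
    """A compact noiseless collection usable by several stages."""
    growth, error = noiseless_models
    hatches = sample_hatch_dates(bimodal_regime, 400, seed=11)
    trips = [dt.date(2021, 4, 10), dt.date(2021, 7, 20)]
    fish, report = realize_fish(hatches, growth, error, trips, seed=12, aged_fraction=0.6)
    return fish, report
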
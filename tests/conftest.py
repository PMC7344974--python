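import numpy as np
import pytest

from expoband import (
    SituationProfile,
    load_category_bands,
    load_factor_table,
    load_fixture,
)


@pytest.fixture(scope="session")
def table():
    return load_factor_table()


@pytest.fixture(scope="session")
def bands():
    return load_category_bands()


@pytest.fixture(scope="session")
def frp_profile():
    return load_fixture("frp_ship_profile")


@pytest.fixture(scope="session")
def summaries_frame():
    return load_fixture("measurement_summaries")


@pytest.fixture(scope="session")
def estimates_frame():
    return load_fixture("model_estimates")


def random_profile(table, rng, situation_id="random"):
    """One uniformly random valid selection per factor."""
    phase = str(rng.choice(["liquid", "solid"]))
    selections = {}
    for f in table.factors:
        labels = f.labels(phase if f.phase_dependent else None)
        selections[f.factor_id] = labels[int(rng.integers(len(labels)))]
    return SituationProfile(situation_id=situation_id, phase=phase, selections=selections)


def no_exposure_profile(table, situation_id="office"):
    """Every factor at its no-exposure class."""
    selections = {}
    for f in table.factors:
        flagged = next(c for c in f.classifications if c.no_exposure)
        selections[f.factor_id] = flagged.label
    return SituationProfile(situation_id=situation_id, phase="liquid", selections=selections)
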
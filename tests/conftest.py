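import pandas as pd
import pytest

from neosurv import CohortConfig, default_catalog, generate_cohort
from neosurv.synthetic_cohort import EPISODE_COLUMNS


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest clean cohort (~2.6k admitted infants) shared across tests."""
    cfg = CohortConfig(n_live_births=20_000, seed=42)
    episodes, truth = generate_cohort(cfg)
    return cfg, episodes, truth


def make_episode(
    infant_id="A",
    unit_id="U001",
    year=2015,
    admission_date="2015-03-01",
    discharge_date="2015-03-05",
    gestational_weeks=40,
    codes="",
):
    return {
        "infant_id": infant_id,
        "unit_id": unit_id,
        "year": year,
        "admission_date": admission_date,
        "discharge_date": discharge_date,
        "gestational_weeks": gestational_weeks,
        "codes": codes,
    }


def episode_frame(rows):
    return pd.DataFrame(rows, columns=list(EPISODE_COLUMNS))


@pytest.fixture
def episode_builder():
    return make_episode, episode_frame
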
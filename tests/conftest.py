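import numpy as np
import pandas as pd
import pytest

import symvert as sv


@pytest.fixture
def toy_survival_frame() -> pd.DataFrame:
    """Six chambers covering all three outcomes across both treatments."""
    return pd.DataFrame(
        {
            "chamber_id": [f"ch{i}" for i in range(1, 7)],
            "treatment": ["roach", "roach", "roach", "no_roach", "no_roach",
                          "no_roach"],
            "flight_id": [1, 1, 2, 1, 2, 2],
            "nest_id": ["f1n1", "f1n1", "f2n1", "f1n2", "f2n1", "f2n2"],
            "day": [3, 5, 8, 10, 12, 15],
            "garden_outcome": ["uncaring", "foundress_dead", "uncaring",
                               "uncaring", "censored", "foundress_dead"],
            "foundress_died": [False, True, False, False, False, True],
            "disturbed": [True, False, True, None, None, None],
        }
    )


@pytest.fixture
def printed_survey_frame() -> pd.DataFrame:
    """Eleven colonies, eight infected, the maximum at 50/719 alates."""
    counts = [
        ("col01", "bfl", 719, 50),
        ("col02", "bfl", 600, 20),
        ("col03", "bfl", 450, 15),
        ("col04", "bfl", 800, 30),
        ("col05", "bfl", 500, 0),
        ("col06", "hb", 900, 40),
        ("col07", "hb", 650, 25),
        ("col08", "hb", 700, 18),
        ("col09", "hb", 550, 22),
        ("col10", "hb", 480, 0),
        ("col11", "hb", 620, 0),
    ]
    return pd.DataFrame(
        counts, columns=["colony_id", "site", "alates_sampled", "alates_with_roach"]
    )


@pytest.fixture
def default_experiment() -> pd.DataFrame:
    return sv.generate_survival_experiment(sv.ExperimentDesign(seed=11))
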
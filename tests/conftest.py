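import numpy as np
import pandas as pd
import pytest

from absst import ItemSpec, ResponseMatrix, RunConfig
from absst.data import ClinicianSurvey


@pytest.fixture
def small_instrument():
    return [
        ItemSpec("a", "first", max_category=4, subscale="symptom_intensity"),
        ItemSpec("b", "second", max_category=4, subscale="symptom_intensity"),
        ItemSpec("c", "third", max_category=4, subscale="impact"),
        ItemSpec("h", "help", max_category=1, subscale="help_seeking"),
    ]


@pytest.fixture
def small_matrix(small_instrument):
    df = pd.DataFrame(
        {
            "a": [0.0, 1, 2, 3, 4, np.nan],
            "b": [1.0, 1, 2, 2, 3, 4],
            "c": [0.0, 2, 2, 4, 4, 0],
            "h": [0.0, 0, 1, 1, 1, 0],
        },
        index=[f"p{i}" for i in range(1, 7)],
    )
    return ResponseMatrix(df, small_instrument)


@pytest.fixture
def small_survey(small_instrument):
    clinicians = ["c1", "c2", "c3"]
    rel = pd.DataFrame(
        {"a": [True, True, True], "b": [True, False, True],
         "c": [False, False, False], "h": [True, True, False]},
        index=clinicians,
    )
    thr = pd.DataFrame(
        {"a": [3.0, 3.0, 4.0], "b": [2.0, np.nan, 2.0],
         "c": [np.nan] * 3, "h": [1.0, 1.0, np.nan]},
        index=clinicians,
    )
    return ClinicianSurvey(rel, thr, small_instrument)


@pytest.fixture
def run_config():
    return RunConfig()
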
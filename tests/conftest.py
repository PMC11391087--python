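import numpy as np
import pandas as pd
import pytest

from neurocohort import CohortTable, default_battery
from neurocohort.cohort import DEMO_COLUMNS


@pytest.fixture(scope="session")
def battery():
    return default_battery()


def make_cohort(battery, groups, scores=None, *, asrs=None, education=None,
                sex=None, rng=None):
    """Hand-build a cohort: `groups` is a list of group labels, `scores`
    an optional {measure: list} overriding the default fill of 10.0."""
    n = len(groups)
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame({
        "id": [f"p{i:03d}" for i in range(n)],
        "group": groups,
        "sex": sex if sex is not None else ["female"] * n,
        "age": 42.0,
        "ses": 2.0,
        "education": education if education is not None else 2.0,
        "birth_risks": ["none" if g == "Control" else "one" for g in groups],
        "asrs": asrs if asrs is not None else 6.0,
    })
    for m in battery.measure_names:
        df[m] = 10.0
    if scores:
        for m, vals in scores.items():
            df[m] = np.asarray(vals, dtype=float)
    return CohortTable(data=df[DEMO_COLUMNS + battery.measure_names],
                       battery=battery)


@pytest.fixture
def tiny_cohort(battery):
    """Three participants, one per non-control group plus a control."""
    return make_cohort(battery, ["cADHD", "cAP", "Non-cAP", "Control"])
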
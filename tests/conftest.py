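import numpy as np
import pytest

import sensiperiod as sp


@pytest.fixture
def tiny_matrix():
    """3 subjects x 2 types x 3 ages with hand-countable exposure."""
    sev = np.zeros((3, 2, 3))
    # subject 0: unexposed
    # subject 1: NVEA severity 2 at ages 13 and 14
    # subject 2: NVEA 1 at age 14, PVA 3 at age 12
    sev[1, 0, 1] = 2.0
    sev[1, 0, 2] = 2.0
    sev[2, 0, 2] = 1.0
    sev[2, 1, 0] = 3.0
    return sp.ExposureMatrix(
        subject_ids=["a", "b", "c"],
        type_labels=["NVEA", "PVA"],
        ages=[12, 13, 14],
        severity=sev,
        stratum=np.array(["F", "M", "F"]),
    )


@pytest.fixture(scope="session")
def single_window_table():
    """A simulated single-window dataset with its planted ground truth."""
    spec = sp.scenario_library(seed=11)["single_window"]
    x, y = sp.simulate_scenario(spec)
    mask = sp.prevalence_filter(x)
    table = sp.build_feature_table(x, mask, y, "continuous")
    planted = [f"{x.type_labels[t]}_{x.ages[a]}" for t, a, _ in spec.effect_cells]
    return table, planted
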
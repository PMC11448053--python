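import numpy as np
import pandas as pd
import pytest

from microstab import FeatureTable, SampleMetadata, TrialConfig, simulate_trial


@pytest.fixture(scope="session")
def small_trial():
    """A compact synthetic trial reused across read-only tests."""
    cfg = TrialConfig(
        n_placebo=6,
        n_treatment=6,
        n_taxa=40,
        n_metabolites=60,
        depth_mean=5000,
        seed=101,
    )
    return simulate_trial(cfg)


@pytest.fixture()
def toy_table():
    data = pd.DataFrame(
        [[1.0, 8.0], [2.0, 4.0], [4.0, 2.0], [8.0, 1.0]],
        index=["f1", "f2", "f3", "f4"],
        columns=["s1", "s2"],
    )
    return FeatureTable(data, kind="counts")


@pytest.fixture()
def toy_metadata():
    samples = pd.DataFrame(
        {
            "subject_id": ["A", "A", "A", "A", "B", "B", "B", "B"],
            "group": ["treatment"] * 4 + ["placebo"] * 4,
            "day": [1, 7, 14, 78] * 2,
        },
        index=[f"{s}.d{d}" for s in "AB" for d in (1, 7, 14, 78)],
    )
    subjects = pd.DataFrame(
        {"serum_baseline": [40.0, 35.0], "serum_end": [75.0, 34.0]},
        index=["A", "B"],
    )
    return SampleMetadata(samples, subjects)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
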
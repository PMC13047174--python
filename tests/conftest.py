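import numpy as np
import pandas as pd
import pytest

from microdyn import FeatureTable, SampleMetadata, SyntheticConfig, simulate_cohort


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    """Scaled-down cohort used across the suite: same structure as the default
    study conditions, fewer subjects/features for speed."""
    params = dict(
        n_subjects={"toddler": 6, "adolescent": 6, "adult": 10},
        n_features=150,
        n_functions=50,
        sequencing_depth=30_000,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_config())


@pytest.fixture()
def tiny_table():
    """Two subjects × three time points, four features, hand-checkable."""
    data = pd.DataFrame(
        [[10, 0, 5, 5],
         [8, 2, 5, 5],
         [9, 1, 4, 6],
         [0, 10, 5, 5],
         [0, 8, 6, 6],
         [1, 9, 5, 5]],
        index=[f"s{i}" for i in range(1, 7)],
        columns=["f1", "f2", "f3", "f4"],
        dtype=float,
    )
    return FeatureTable(data, mode="counts")


@pytest.fixture()
def tiny_meta():
    md = pd.DataFrame({
        "subject_id": ["A", "A", "A", "B", "B", "B"],
        "group": ["toddler", "toddler", "toddler", "adult", "adult", "adult"],
        "timepoint": [1, 2, 3, 1, 2, 3],
    }, index=[f"s{i}" for i in range(1, 7)])
    md.index.name = "sample_id"
    return SampleMetadata(md)
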
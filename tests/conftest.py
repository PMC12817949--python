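import numpy as np
import pandas as pd
import pytest

from ecoassembly.core_io import CommunityTable, SampleMetadata


@pytest.fixture
def small_counts() -> CommunityTable:
    """3 taxa x 2 samples, hand-enumerable."""
    df = pd.DataFrame(
        {"S1": [6, 2, 0], "S2": [2, 2, 4]},
        index=["ASV_1", "ASV_2", "ASV_3"],
    )
    return CommunityTable(df, mode="counts")


@pytest.fixture
def random_counts() -> CommunityTable:
    """20 taxa x 8 samples of Poisson counts (seeded)."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.poisson(20, size=(20, 8)),
        index=[f"T{i:03d}" for i in range(20)],
        columns=[f"S{j}" for j in range(8)],
    )
    return CommunityTable(df, mode="counts")


@pytest.fixture
def two_group_meta() -> SampleMetadata:
    groups = pd.Series(
        {"S0": "A", "S1": "A", "S2": "A", "S3": "A", "S4": "B", "S5": "B", "S6": "B", "S7": "B"},
        name="group",
    )
    return SampleMetadata(groups)
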
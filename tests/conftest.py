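import numpy as np
import pytest
from hypothesis import settings

import ezset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def worked_summary() -> ezset.JudgmentSummary:
    """The fictitious 7-member panel: means and SEs as printed."""
    return ezset.JudgmentSummary(x_l=42.0, x_h=60.43, se_l=3.74, se_h=8.34, n=7)


@pytest.fixture
def small_dataset() -> ezset.PrimaryDataset:
    """A tiny deterministic 2-station, 4-panelist rectangular dataset."""
    return ezset.PrimaryDataset(
        stations=("A", "B"),
        panelist_ids=("p1", "p2", "p3", "p4"),
        l_marks=np.array([[40.0, 8.0], [42.0, 9.0], [44.0, 10.0], [41.0, 8.5]]),
        h_marks=np.array([[55.0, 12.0], [60.0, 13.0], [65.0, 14.0], [58.0, 12.5]]),
    )


@pytest.fixture
def preset_models():
    return ezset.table1_like_preset()
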
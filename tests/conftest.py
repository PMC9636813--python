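import numpy as np
import pandas as pd
import pytest

from phytomarker import (ActivityTable, PeakTable, generate_tables,
                         paper_like_config)


@pytest.fixture(scope="session")
def paper_like():
    """One default-scenario cohort (31 samples, 22 compounds, 3 assays)."""
    config = paper_like_config(seed=1)
    peaks, acts = generate_tables(config)
    return config, peaks, acts


@pytest.fixture
def small_tables():
    """Tiny aligned pair for hand-checkable computations."""
    rng = np.random.default_rng(7)
    peaks = PeakTable(pd.DataFrame(
        rng.uniform(1, 10, size=(5, 4)),
        index=[f"s{i}" for i in range(5)],
        columns=["1", "2", "3", "4"]))
    acts = ActivityTable(pd.DataFrame(
        rng.uniform(10, 90, size=(5, 2)),
        index=[f"s{i}" for i in range(5)],
        columns=["DPPH", "FRAP"]))
    return peaks, acts
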
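import numpy as np
import pandas as pd
import pytest

from capranir import SpectraSet, SyntheticConfig, WavenumberGrid, generate_dataset


@pytest.fixture(scope="session")
def small_grid():
    # 5-point toy grid, spacing 2
    return WavenumberGrid(start=4000.0, stop=4008.0, spacing=2.0)


@pytest.fixture()
def small_set(small_grid):
    rng = np.random.default_rng(0)
    n = 6
    return SpectraSet(
        grid=small_grid,
        matrix=rng.uniform(0.1, 1.0, size=(n, small_grid.n_points)),
        sample_id=np.repeat(["s1", "s2", "s3"], 2),
        replicate=np.tile([1, 2], 3),
        breed=np.repeat(["A", "A", "B"], 2),
        sex=np.repeat(["M", "F", "M"], 2),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The full synthetic cohort at seed 42 (32 samples x 3 replicates)."""
    return generate_dataset(SyntheticConfig(), seed=42)


@pytest.fixture(scope="session")
def serrana_profile():
    """Published Serrana breed-mean fatty-acid column."""
    from capranir.reference_data import FA_MEANS

    return dict(FA_MEANS["Serrana"])
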
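import numpy as np
import pytest

import scarline as sl
from scarline import synthetic_data as sd


@pytest.fixture(scope="session")
def small_layout() -> sl.GenomeLayout:
    return sl.GenomeLayout.from_dict({"chr1": 2_000_000})


@pytest.fixture(scope="session")
def grid1kb(small_layout) -> sl.WindowGrid:
    return sl.make_windows(small_layout, 1_000)


@pytest.fixture(scope="session")
def landscape(small_layout) -> sd.ReplicationLandscape:
    return sd.simulate_landscape(small_layout, n_zones=10, seed=1)


@pytest.fixture(scope="session")
def rfd(landscape, grid1kb) -> sl.Track:
    return landscape.rfd_track(grid1kb)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
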
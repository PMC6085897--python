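import numpy as np
import pytest

from alpaca_cwas.atlas import build_phantom_atlas
from alpaca_cwas.cohort import CohortSpec, PlantedEffect

ONE_PER_GROUP = {"Fro": 1, "Occ": 1, "Par": 1, "Sub": 1, "Temp": 1}

# compact phantom geometry used throughout the suite: 10 mirrored regions of
# 27 voxels on a 16x12x8 grid
COMPACT = dict(grid_shape=(16, 12, 8), block_shape=(3, 3, 3))


@pytest.fixture(scope="session")
def small_atlas():
    return build_phantom_atlas((16, 12, 8), ONE_PER_GROUP, block_shape=(3, 3, 3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def compact_spec(**kw) -> CohortSpec:
    """Cohort spec on the compact phantom; keyword overrides pass through."""
    base = dict(
        n_subjects=10,
        seed=0,
        motion_spike_prob=0.0,
        regions_per_group=dict(ONE_PER_GROUP),
        **COMPACT,
    )
    base.update(kw)
    return CohortSpec(**base)


def planted(edge, **kw) -> PlantedEffect:
    return PlantedEffect(edge=tuple(edge), **kw)
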
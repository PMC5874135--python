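import numpy as np
import pytest
from hypothesis import settings

import seedpls
from seedpls.seeds import SeedSpec, SeedTable
from seedpls.simulate import PatternSpec, SimulationConfig

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: Compact grid used by unit tests: 12x14x12 voxels at 6 mm, world origin at
#: the grid centre.  Seeds for it must stay within ~±30 mm.
SMALL_GRID = dict(grid_shape=(12, 14, 12), voxel_size_mm=6.0, center_mm=(0.0, 0.0, 0.0))


def small_seed_table() -> SeedTable:
    """Two four-seed networks that fit the compact test grid."""
    # coordinates sit exactly on voxel centers of the 6 mm test grid
    rows = [
        ("ventral_attention", -9.0, 3.0, 3.0, "L", "test ACC"),
        ("ventral_attention", 9.0, 3.0, 3.0, "R", "test ACC"),
        ("ventral_attention", -15.0, -9.0, 3.0, "L", "test insula"),
        ("ventral_attention", 15.0, -9.0, 3.0, "R", "test insula"),
        ("visual", -9.0, -15.0, -3.0, "L", "test V1"),
        ("visual", 9.0, -15.0, -3.0, "R", "test V1"),
        ("visual", -15.0, 9.0, -9.0, "L", "test extrastriate"),
        ("visual", 15.0, 9.0, -9.0, "R", "test extrastriate"),
    ]
    return SeedTable(SeedSpec(*r) for r in rows)


def small_config(n_per_group=5, rng_seed=7, **overrides) -> SimulationConfig:
    """Single stable pattern on the compact grid."""
    pattern = PatternSpec(
        kind="stable_decline",
        amplitude=0.5,
        network="ventral_attention",
        extra_centers_mm=((0.0, 12.0, 8.0),),
        blob_fwhm_mm=12.0,
    )
    kw = dict(SMALL_GRID)
    kw.update(overrides)
    return SimulationConfig(
        n_per_group=n_per_group, patterns=(pattern,), rng_seed=rng_seed, **kw
    )


@pytest.fixture(scope="session")
def tiny_table():
    return small_seed_table()


@pytest.fixture(scope="session")
def small_dataset(tiny_table):
    return seedpls.generate_dataset(small_config(), seed_table=tiny_table)


@pytest.fixture(scope="session")
def small_analysis(small_dataset, tiny_table):
    """One PLS decomposition of the small dataset (no resampling)."""
    y = seedpls.network_seed_average(small_dataset, tiny_table, "ventral_attention").values
    groups = seedpls.assign_groups(small_dataset.ages)
    X = small_dataset.voxel_matrix
    Xn, Yn = seedpls.group_normalize(X, y, groups)
    Z = seedpls.covariance_stack(Xn, Yn, groups)
    return dict(y=y, groups=groups, X=X, Z=Z, lvset=seedpls.decompose(Z))
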
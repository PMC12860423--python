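import pytest

import agnomap as ag

GRID = (40, 48, 40)


@pytest.fixture(scope="session")
def atlas116():
    """116-region parcellation on the desk-scale grid."""
    atlas = ag.generate_atlas(GRID, 116, seed=1)
    atlas.validate()
    return atlas


@pytest.fixture(scope="session")
def atlas30():
    """30-region parcellation used by the null-calibration experiments."""
    atlas = ag.generate_atlas(GRID, 30, seed=5)
    atlas.validate()
    return atlas


@pytest.fixture(scope="session")
def tiny_atlas():
    """4 regions on a 20^3 grid for cheap cohort-level tests."""
    return ag.generate_atlas((20, 20, 20), 4, seed=2)


@pytest.fixture(scope="session")
def null_cohort60(atlas30):
    """60 healthy controls, single site, no planted effect, no corruption."""
    spec = ag.EffectSpec(noise_sd=0.05)
    cohort, volumes = ag.generate_cohort(atlas30, {"SITE1": (60, 0)}, spec, seed=11)
    return cohort, volumes


@pytest.fixture(scope="session")
def null_hc_asc_cohort(tiny_atlas):
    """Small two-group cohort with no true group difference."""
    spec = ag.EffectSpec(noise_sd=0.05)
    cohort, volumes = ag.generate_cohort(tiny_atlas, {"SITE1": (15, 15)}, spec, seed=21)
    return cohort, volumes

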
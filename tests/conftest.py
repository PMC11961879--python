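import numpy as np
import pytest

from mdoseqa.core import VolumeGrid
from mdoseqa.phantom_sim import (
    CohortRanges,
    PerturbationSpec,
    PhantomSpec,
    generate_ct,
    generate_rtdose,
    perturb_to_mdose,
    generate_cohort,
)

# Desk-scale phantom small enough for fast unit tests (levels<=3 networks).
TINY_SPEC = PhantomSpec(
    grid_shape=(16, 32, 32),
    spacing=(4.5, 4.5, 4.5),
    body_semiaxes=(26.0, 60.0, 55.0),
    ptv_center=(0.0, 6.0, 8.0),
    ptv_semiaxes=(11.0, 15.0, 13.0),
    dose_falloff_sigma=12.0,
)


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return TINY_SPEC


@pytest.fixture(scope="session")
def tiny_case(tiny_spec):
    ct, structures = generate_ct(tiny_spec, seed=11)
    rtdose = generate_rtdose(tiny_spec, structures)
    mdose = perturb_to_mdose(rtdose, ct, structures, PerturbationSpec(seed=11))
    return ct, structures, rtdose, mdose


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    """Eight jittered cases on the tiny grid, with default perturbations."""
    return generate_cohort(
        8,
        CohortRanges(base=tiny_spec, ptv_center_offset=3.0),
        PerturbationSpec(),
        seed=42,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)


def random_volume(rng, n=8, spacing=(3.0, 3.0, 3.0), scale=70.0) -> VolumeGrid:
    return VolumeGrid(rng.random((n, n, n)) * scale, spacing)
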
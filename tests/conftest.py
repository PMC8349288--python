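"""Shared fixtures: the standard seeded step-motion scenario on a disk phantom."""

import pytest

from unghost import (
    CorrectionConfig,
    PhantomSpec,
    apply_motion,
    correct,
    forward_kspace,
    generate_phantom,
    inverse_kspace,
    make_trajectory,
    true_support,
)

STANDARD_SIZE = 128
STEP_PARAMS = {"amplitude_px": 4.0, "onset_fraction": 0.5, "axis": "x"}


@pytest.fixture(scope="session")
def disk_spec():
    return PhantomSpec(size=STANDARD_SIZE, model="disk")


@pytest.fixture(scope="session")
def disk_phantom(disk_spec):
    return generate_phantom(disk_spec)


@pytest.fixture(scope="session")
def disk_support(disk_spec):
    return true_support(disk_spec)


@pytest.fixture(scope="session")
def step_trajectory():
    return make_trajectory("step", STEP_PARAMS, STANDARD_SIZE)


@pytest.fixture(scope="session")
def corrupted_kspace(disk_phantom, step_trajectory):
    return apply_motion(forward_kspace(disk_phantom), step_trajectory)


@pytest.fixture(scope="session")
def corrupted_recon(corrupted_kspace):
    return inverse_kspace(corrupted_kspace)


@pytest.fixture(scope="session")
def standard_result(corrupted_kspace, disk_support):
    """Oracle-ROI cumulative correction of the standard scenario."""
    return correct(corrupted_kspace, CorrectionConfig(roi_method="oracle"),
                   roi_override=disk_support)
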
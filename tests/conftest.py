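"""Shared fixtures: synthetic scenes generated once per session."""

import numpy as np
import pytest

from memquant.optics import OpticalModel
from memquant.simulate import CellGroundTruth, StageModel, generate_bead_zstack

TWO_BEAD_SCENE = dict(
    beads=[
        {"center_px": (30.0, 32.0), "radius_nm": 1875.0},
        {"center_px": (30.0, 78.0), "radius_nm": 1400.0},
    ],
    impurity={"center_px": (78.0, 30.0), "amplitude": 400.0},
)
BEAD_A_ROI = (15, 17, 30, 30)
BEAD_B_ROI = (15, 63, 30, 30)
IMPURITY_ROI = (71, 23, 15, 15)


def make_calibration_scene(seed=0, noise="poisson", factor=1.17, step_nm=20.0):
    """Two beads + surface impurity, scanned from below the glass to past the
    larger bead's equator."""
    optical = OpticalModel(noise=noise)
    stage = StageModel(axial_scale_factor=factor)
    reported = np.arange(-400.0, 2401.0, step_nm)
    stack, truth = generate_bead_zstack(
        optical, stage, reported, seed=seed, **TWO_BEAD_SCENE
    )
    return stack, truth


@pytest.fixture(scope="session")
def noiseless_scene():
    return make_calibration_scene(seed=1, noise="none")


@pytest.fixture(scope="session")
def poisson_scene():
    return make_calibration_scene(seed=2, noise="poisson")


@pytest.fixture(scope="session")
def small_cell_truth():
    """Reduced-height cell geometry for fast pipeline tests."""
    return CellGroundTruth.default(n_timepoints=6, interval_s=300.0, shape=(64, 128))
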
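"""Reference-library tracking: lookup accuracy, controller, repeatability."""

import numpy as np
import pytest

from memquant.optics import OpticalModel, apply_noise, render_bead
from memquant.simulate import StageModel, generate_bead_zstack
from memquant.tracking import (
    ReferenceLibrary,
    TrackedBead,
    build_library,
    correction_controller,
    estimate_position,
    find_basolateral_plane,
    repeatability,
    run_tracking_experiment,
)
from memquant.types import BeadLostError, IntensityMap, ScanSchedule

FACTOR = 1.17
BEAD_Z = 1875.0  # bead center height above the glass, nm
LIB_START = BEAD_Z + 2300.0  # library bottom, calibrated nm (on the defocus cone)
ROI = (35, 35, 41, 41)


def make_library(noise="poisson", seed=42, span=4680.0):
    """Library source stack recorded at 23 nm calibrated spacing on one side
    of the bead (the defocus cone), as for a live tracking session."""
    optical = OpticalModel(noise=noise)
    stage = StageModel(axial_scale_factor=FACTOR)
    n = int(span / 23.0) + 5
    reported = (LIB_START / FACTOR) + (23.0 / FACTOR) * np.arange(n)
    stack, _ = generate_bead_zstack(
        optical, stage, reported, seed=seed,
        beads=[{"center_px": (55.0, 55.0), "radius_nm": 1875.0}],
    )
    return build_library(stack, FACTOR, spacing=23.0, span=span, roi=ROI, start=LIB_START)


def render_live(z, noise="none", rng=None):
    o = OpticalModel(noise=noise)
    img = np.full((41, 41), o.background)
    render_bead(o, z - BEAD_Z, (41, 41), (20.0, 20.0), radius=1875.0, out=img)
    return apply_noise(img, o, rng or np.random.default_rng(0))


@pytest.fixture(scope="module")
def library():
    return make_library()


@pytest.fixture(scope="module")
def clean_library():
    return make_library(noise="none")


class TestBuildLibrary:
    def test_template_count_full_span(self, library):
        assert library.n_templates == int(np.floor(4680 / 23)) + 1 == 204

    def test_template_count_minimal_span(self):
        lib = make_library(span=46.0)
        assert lib.n_templates == 3

    def test_positions_reproduce_grid(self, library):
        grid = LIB_START + 23.0 * np.arange(204)
        assert np.max(np.abs(library.positions - grid)) < 0.23

    def test_span_exceeding_stack_rejected(self):
        optical = OpticalModel(noise="none")
        stage = StageModel(axial_scale_factor=FACTOR)
        reported = (LIB_START / FACTOR) + (23.0 / FACTOR) * np.arange(50)
        stack, _ = generate_bead_zstack(
            optical, stage, reported, seed=0,
            beads=[{"center_px": (55.0, 55.0), "radius_nm": 1875.0}],
        )
        with pytest.raises(ValueError):
            build_library(stack, FACTOR, spacing=23.0, span=4680.0, roi=ROI)

    def test_nonuniform_positions_rejected(self):
        pos = np.array([0.0, 23.0, 50.0])
        with pytest.raises(ValueError):
            ReferenceLibrary(np.zeros((3, 5, 5)), pos, spacing=23.0, span=46.0)


class TestEstimatePosition:
    def test_exact_on_every_template(self, library):
        """A live image equal to a stored template returns that template's
        grid position with zero error."""
        for k in (0, 50, 120, 203):
            pos, score = estimate_position(library.templates[k], library)
            assert pos == library.positions[k]
            assert score == pytest.approx(1.0)

    def test_midpoint_noiseless_within_quarter_spacing(self, library):
        z = float(library.positions[100]) + 11.5
        pos, _ = estimate_position(render_live(z), library)
        assert abs(pos - z) <= 23.0 / 4.0

    def test_locally_unbiased_over_span(self, library):
        """Mean signed error over a uniform grid of true positions is below
        spacing/10."""
        zs = np.linspace(library.positions[3], library.positions[-4], 41)
        errs = [estimate_position(render_live(z), library)[0] - z for z in zs]
        assert abs(np.mean(errs)) <= 2.3

    def test_poisson_rms_below_20nm(self, library):
        """Repeatability-limiting estimation noise at generator-default SNR:
        RMS error < 20 nm over 100 draws."""
        rng = np.random.default_rng(11)
        z = float(library.positions[60]) + 7.0
        errs = [
            estimate_position(render_live(z, "poisson", rng), library)[0] - z
            for _ in range(100)
        ]
        assert np.sqrt(np.mean(np.square(errs))) < 20.0

    def test_unmatched_image_raises_bead_lost(self, library):
        rng = np.random.default_rng(0)
        noise_img = rng.uniform(0, 100, (41, 41))
        with pytest.raises(BeadLostError):
            estimate_position(noise_img, library)


class TestController:
    @pytest.mark.parametrize("estimate,target,deadband,expected", [
        (100.0, 0.0, 10.0, -100.0),
        (3.0, 0.0, 5.0, 0.0),
        (-40.0, -25.0, 5.0, 15.0),
    ])
    def test_deadband_proportional(self, estimate, target, deadband, expected):
        assert correction_controller(estimate, target, deadband) == pytest.approx(expected)


class TestTrackingExperiment:
    def test_default_protocol_visits_15_planes(self, library):
        trace = run_tracking_experiment(
            StageModel(), OpticalModel(noise="poisson"), ScanSchedule(), library,
            seed=0, bead=TrackedBead(BEAD_Z, (20.0, 20.0), 1875.0),
            baseline=BEAD_Z + 2400.0,
        )
        # 5 scans x 3 planes; each inter-scan park shares the baseline target
        # with the following scan's first hold, so 15 constant-target runs
        runs = (trace["target_nm"].diff() != 0).cumsum()
        assert runs.nunique() == 15

    def test_zero_noise_zero_delta_gp_during_holds(self, clean_library):
        """Perfect stage + noiseless optics + on-grid targets: the estimate
        equals the target exactly at every hold sample."""
        stage = StageModel(drift_rate=0.0, drift_random_walk_sd=0.0, backlash=0.0)
        sched = ScanSchedule(plane_offsets=[0.0, 23.0 * 25, 23.0 * 100])
        trace = run_tracking_experiment(
            stage, OpticalModel(noise="none"), sched, clean_library,
            seed=0, bead=TrackedBead(BEAD_Z, (20.0, 20.0), 1875.0),
            baseline=float(clean_library.positions[4]),
        )
        assert np.max(np.abs(trace["delta_gp_nm"])) == 0.0

    def test_backlash_transient_corrected_within_two_updates(self, clean_library):
        stage = StageModel(drift_rate=0.0, drift_random_walk_sd=0.0, backlash=100.0)
        sched = ScanSchedule(plane_offsets=[0.0, 23.0 * 22, 0.0], n_scans=1,
                             inter_scan_delay=0.0)
        trace = run_tracking_experiment(
            stage, OpticalModel(noise="none"), sched, clean_library,
            seed=0, bead=TrackedBead(BEAD_Z, (20.0, 20.0), 1875.0),
            baseline=float(clean_library.positions[4]), deadband=5.0,
        )
        run_id = (trace["target_nm"].diff() != 0).cumsum()
        last = trace[run_id == run_id.iloc[-1]]["delta_gp_nm"].to_numpy()
        assert abs(last[0]) == pytest.approx(100.0, abs=1.0)  # reversal undershoot
        assert np.all(np.abs(last[2:]) <= 5.0)

    def test_closed_loop_rms_below_20nm(self, library):
        trace = run_tracking_experiment(
            StageModel(), OpticalModel(noise="poisson"), ScanSchedule(), library,
            seed=1, bead=TrackedBead(BEAD_Z, (20.0, 20.0), 1875.0),
            baseline=BEAD_Z + 2400.0,
        )
        stats = repeatability(trace)
        assert stats["rms_hold_error"] < 20.0

    def test_plane_outside_span_rejected(self, library):
        with pytest.raises(ValueError):
            run_tracking_experiment(
                StageModel(), OpticalModel(), ScanSchedule(), library,
                seed=0, bead=TrackedBead(BEAD_Z, (20.0, 20.0), 1875.0),
                baseline=float(library.positions[-1]),
            )


class TestRepeatability:
    def test_no_hold_samples_rejected(self):
        import pandas as pd
        trace = pd.DataFrame({
            "t_s": [0.0], "target_nm": [0.0], "measured_nm": [0.0],
            "stage_nm": [0.0], "delta_gp_nm": [0.0], "phase": ["moving"],
            "true_nm": [0.0],
        })
        with pytest.raises(ValueError):
            repeatability(trace)


class TestFindBasolateralPlane:
    def test_membrane_plane_found(self):
        rng = np.random.default_rng(0)
        positions = np.arange(11) * 200.0
        maps = []
        for i in range(11):
            base = 10.0 + 90.0 * np.exp(-((i - 5) ** 2) / 2.0)
            maps.append(IntensityMap(np.full((8, 8), base) + rng.normal(0, 0.1, (8, 8))))
        pos, at_edge = find_basolateral_plane(maps, positions)
        assert pos == 1000.0
        assert not at_edge

    def test_monotone_stack_flags_edge(self):
        maps = [IntensityMap(np.full((4, 4), float(i))) for i in range(5)]
        pos, at_edge = find_basolateral_plane(maps, np.arange(5) * 100.0)
        assert at_edge

    def test_tie_breaks_to_lower_plane(self):
        vals = [1.0, 5.0, 5.0, 1.0, 0.5]
        maps = [IntensityMap(np.full((4, 4), v)) for v in vals]
        pos, _ = find_basolateral_plane(maps, np.arange(5) * 100.0)
        assert pos == 100.0

    def test_too_few_planes_rejected(self):
        with pytest.raises(ValueError):
            find_basolateral_plane([IntensityMap(np.zeros((4, 4)))] * 2, [0.0, 1.0])
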
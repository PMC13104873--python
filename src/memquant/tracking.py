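"""Reference-library focal tracking and closed-loop axial correction.

A fiducial bead adsorbed to the coverslip is imaged once over the focal range
of interest at uniform calibrated spacing, forming a reference library.  The
current focal plane is then inferred from a live bead image by comparing it
to every template (zero-normalized cross-correlation, ZNCC) and refining the
best match sub-spacing with a 3-point parabola over the score curve.  A
proportional controller with a deadband commands corrective stage moves; the
whole loop is exercised here purely in simulation against the synthetic stage
and optics models.

The matching metric sits behind ``similarity_scores`` so alternatives (sum of
squared differences, radial-profile matching) can be swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import OpticalModel, apply_noise, render_bead
from .simulate import StageModel, protocol_segments, simulate_protocol
from .types import BeadLostError, BeadZStack, ScanSchedule


@dataclass
class ReferenceLibrary:
    """Bead templates indexed by calibrated focal position (nm), uniformly
    spaced.  Templates are background-subtracted bead ROIs; a zero-mean,
    unit-norm flattened copy is precomputed for ZNCC lookups."""

    templates: np.ndarray  # n_templates x rows x cols
    positions: np.ndarray  # calibrated nm, strictly increasing, uniform
    spacing: float  # nm
    span: float  # nm
    _zncc_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.templates = np.asarray(self.templates, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.templates.ndim != 3 or self.templates.shape[0] != self.positions.size:
            raise ValueError("one position per template required")
        d = np.diff(self.positions)
        if np.any(d <= 0):
            raise ValueError("positions must be strictly increasing")
        if d.size and (d.max() - d.min()) > 0.01 * self.spacing:
            raise ValueError("positions must be uniform to <1% of spacing")
        flat = self.templates.reshape(self.templates.shape[0], -1)
        flat = flat - flat.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(flat, axis=1)
        norms[norms == 0] = 1.0
        self._zncc_matrix = flat / norms[:, None]

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    @property
    def roi_shape(self) -> tuple[int, int]:
        return self.templates.shape[1:]


def build_library(
    stack: BeadZStack,
    factor: float,
    spacing: float = 23.0,
    span: float = 4680.0,
    roi=None,
    start: float | None = None,
) -> ReferenceLibrary:
    """Build a reference library from a calibrated bead z-stack.

    Positions are the stack's reported positions times the calibration
    ``factor``; templates are taken at uniform calibrated spacing starting at
    ``start`` (default: the first calibrated position), selecting the nearest
    source frame for each grid point.  ``roi`` = (row, col, height, width)
    crops the bead window; None uses the full frame.  Templates are
    background-subtracted (per-frame 10th percentile).
    """
    calibrated = stack.reported_positions * factor
    order = np.argsort(calibrated)
    calibrated = calibrated[order]
    lo = calibrated[0] if start is None else float(start)
    n = int(np.floor(span / spacing)) + 1
    grid = lo + spacing * np.arange(n)
    if grid[-1] > calibrated[-1] + 0.5 * spacing or grid[0] < calibrated[0] - 0.5 * spacing:
        raise ValueError("requested span exceeds the calibrated stack range")
    nearest = np.argmin(np.abs(calibrated[None, :] - grid[:, None]), axis=1)
    frames = stack.frames[order][nearest]
    if roi is not None:
        r0, c0, h, w = roi
        frames = frames[:, r0:r0 + h, c0:c0 + w]
    templates = frames - np.percentile(frames, 10, axis=(1, 2), keepdims=True)
    return ReferenceLibrary(templates, grid, spacing=spacing, span=span)


def similarity_scores(live: np.ndarray, library: ReferenceLibrary) -> np.ndarray:
    """Zero-normalized cross-correlation of the live ROI against every
    template.  Scores lie in [-1, 1]; 1 is a perfect (affine-intensity) match.
    ZNCC is insensitive to illumination drift and background offset."""
    v = np.asarray(live, dtype=float).ravel()
    if v.size != library._zncc_matrix.shape[1]:
        raise ValueError("live image geometry differs from the library ROI")
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        return np.zeros(library.n_templates)
    return library._zncc_matrix @ (v / n)


def estimate_position(
    live: np.ndarray, library: ReferenceLibrary, score_threshold: float = 0.5
) -> tuple[float, float]:
    """Estimate the current focal position (nm) from a live bead image.

    Returns ``(position, peak_score)``.  The best-scoring template is refined
    by a parabola through it and its two neighbors; an exact template match
    returns that template's grid position exactly.  A peak score below
    ``score_threshold`` raises :class:`BeadLostError`.
    """
    s = similarity_scores(live, library)
    j = int(np.argmax(s))
    peak = float(s[j])
    if peak < score_threshold:
        raise BeadLostError(f"peak ZNCC {peak:.3f} below threshold {score_threshold}")
    if peak >= 1.0 - 1e-12 or j == 0 or j == library.n_templates - 1:
        return float(library.positions[j]), peak
    denom = s[j - 1] - 2.0 * s[j] + s[j + 1]
    offset = 0.0 if denom >= 0 else 0.5 * (s[j - 1] - s[j + 1]) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    return float(library.positions[j] + offset * library.spacing), peak


def correction_controller(estimate: float, target: float, deadband: float = 5.0) -> float:
    """Proportional (gain 1) correction with a deadband: the commanded stage
    move that cancels the measured error, or 0 inside the deadband."""
    err = estimate - target
    return -err if abs(err) > deadband else 0.0


@dataclass
class TrackedBead:
    """Scene geometry for rendering live images during a simulated run: the
    bead's axial center (calibrated nm) and its (row, col) axis within the
    library ROI."""

    axial_center: float
    center_px: tuple[float, float]
    radius: float | None = None  # None: use the optical model's radius


def run_tracking_experiment(
    stage: StageModel,
    optical: OpticalModel,
    schedule: ScanSchedule,
    library: ReferenceLibrary,
    seed: int,
    bead: TrackedBead,
    baseline: float,
    controller_on: bool = True,
    hold_duration: float = 27.0,
    deadband: float = 5.0,
    update_interval: float = 1.0,
    score_threshold: float = 0.5,
) -> pd.DataFrame:
    """Simulate the full multi-plane protocol with image-based tracking.

    Per update the bead is rendered at the current true focal position with
    the optical model's noise, its position estimated against the library,
    and (closed loop) a correction commanded when the error exceeds the
    deadband.  Returns the trace of the three recorded streams (measured
    position, stage readout, measured-minus-target) plus the hidden true
    position; ``trace.attrs['bead_lost']`` flags a truncated run.
    """
    lo, hi = library.positions[0], library.positions[-1]
    for off in schedule.plane_offsets:
        if not (lo <= baseline + off <= hi):
            raise ValueError("scheduled plane outside the library span")
    shape = library.roi_shape

    def estimator(z_true: float, rng: np.random.Generator) -> float:
        img = np.full(shape, optical.background)
        render_bead(optical, z_true - bead.axial_center, shape, bead.center_px,
                    radius=bead.radius, out=img)
        img = apply_noise(img, optical, rng)
        pos, _score = estimate_position(img, library, score_threshold=score_threshold)
        return pos

    segments = protocol_segments(schedule, baseline=baseline, hold_duration=hold_duration)
    return simulate_protocol(
        stage, segments, seed=seed, estimator=estimator,
        controller_on=controller_on, deadband=deadband, update_interval=update_interval,
    )


def repeatability(trace: pd.DataFrame) -> dict:
    """Hold-phase positioning statistics of a tracking trace.

    Settle windows after each move are excluded (they carry ``phase ==
    "moving"``; during moves the measured-target difference reflects dynamics,
    not drift).  ``uncorrected_drift`` is, per hold segment, the change in
    measured position minus the change in stage readout, summed: the drift the
    controller had to compensate (closed loop) or that accumulated freely
    (open loop).
    """
    hold = trace[trace["phase"] == "holding"]
    if hold.empty:
        raise ValueError("trace contains no hold samples")
    dgp = hold["delta_gp_nm"].to_numpy()
    # Drift accumulates while the target is stationary; commanded plane
    # changes between runs are excluded, while corrections within a run show
    # up identically in the measured position and the stage readout and so
    # cancel.  Group by constant-target runs over all samples.
    run_id = (trace["target_nm"].diff() != 0).cumsum()
    drift = 0.0
    for _, seg in trace.groupby(run_id):
        drift += (seg["measured_nm"].iloc[-1] - seg["measured_nm"].iloc[0]) - (
            seg["stage_nm"].iloc[-1] - seg["stage_nm"].iloc[0]
        )
    return {
        "rms_hold_error": float(np.sqrt(np.mean(dgp**2))),
        "max_hold_error": float(np.max(np.abs(dgp))),
        "uncorrected_drift": float(drift),
    }


def find_basolateral_plane(maps, positions) -> tuple[float, bool]:
    """Locate the basolateral membrane as the plane of maximum total
    fluorescence in an exploratory z-stack.

    ``maps`` is a sequence of IntensityMap (or 2D arrays) and ``positions``
    their axial positions (nm).  Returns ``(position, at_edge)``; ``at_edge``
    warns that the maximum sits at the stack boundary, i.e. the scanned range
    may not bracket the membrane.  Ties break toward the lower plane.
    """
    positions = np.asarray(positions, dtype=float)
    if len(maps) < 3 or positions.size != len(maps):
        raise ValueError("need >= 3 planes with one position each")
    totals = np.array([np.sum(getattr(m, "values", m)) for m in maps])
    order = np.argsort(positions)
    totals, positions = totals[order], positions[order]
    j = int(np.argmax(totals))  # argmax returns the first (lower) of a tie
    return float(positions[j]), bool(j == 0 or j == totals.size - 1)
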
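"""Synthetic-data generators with known ground truth.

Three families of inputs are emulated:

* reflected-light z-stacks of coverslip-adsorbed beads (plus a sub-diffraction
  glass-surface impurity) versus reported objective position, where the true
  focal displacement is the reported displacement times the stage's axial
  scale factor;
* objective-stage traces under thermal drift (deterministic ramp plus Gaussian
  random walk) and mechanical backlash (constant undershoot on drive-direction
  reversal), with or without a closed correction loop;
* two-fluorophore spectral image time series of a cell cross-section (membrane
  Gaussian ridge plus cytoplasmic sigmoid pool) and its basolateral membrane
  (uniform receptor field developing puncta after agonist treatment), with a
  conserved-total transfer of arrestin amplitude from cytoplasm to membrane.

Every generator returns a machine-readable ground-truth record sufficient for
parameter-recovery tests of the downstream modules.  Fixed seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .optics import OpticalModel, apply_noise, render_bead, render_impurity
from .types import BeadLostError, BeadZStack, ScanSchedule, SpectralStack

AVOGADRO_PER_UM3_PER_UM = 0.602214076  # molecules per um^3 at 1 uM


@dataclass
class StageModel:
    """Motorized objective-stage error model.

    ``axial_scale_factor`` is the true focal displacement per unit reported
    displacement (dimensionless).  ``backlash`` (nm) is the undershoot applied
    when the drive direction reverses.  Thermal drift is a deterministic ramp
    ``drift_rate`` (nm/s) plus a Gaussian random walk of standard deviation
    ``drift_random_walk_sd`` (nm per sqrt-second).
    """

    axial_scale_factor: float = 1.17
    backlash: float = 150.0  # nm
    drift_rate: float = 200.0 / 60.0  # nm/s (~2 um over a 10-min protocol)
    drift_random_walk_sd: float = 5.0  # nm / sqrt(s)
    settle_time: float = 2.0  # s

    def __post_init__(self) -> None:
        if self.axial_scale_factor <= 0:
            raise ValueError("axial_scale_factor must be > 0")
        if self.backlash < 0:
            raise ValueError("backlash must be >= 0")


# ---------------------------------------------------------------------------
# bead z-stacks


def generate_bead_zstack(
    model: OpticalModel,
    stage: StageModel,
    reported_positions,
    seed: int,
    beads=None,
    impurity=None,
    shape: tuple[int, int] = (110, 110),
):
    """Render a reflected-light z-stack of one or more coverslip beads.

    ``beads`` is a list of ``{"center_px": (row, col), "radius_nm": R}``; each
    bead sits on the glass so its center lies at true z = R.  ``impurity``
    is ``{"center_px": (row, col), "amplitude": a}`` for a sub-diffraction
    surface spot at true z = 0, or None to omit it.  Frames carry *reported*
    positions only; the ground-truth record carries the axial scale factor and
    true bead-center heights.

    Returns ``(BeadZStack, truth_record)``.
    """
    reported = np.asarray(reported_positions, dtype=float)
    if reported.size == 0:
        raise ValueError("reported_positions must not be empty")
    if beads is None:
        beads = [{"center_px": (shape[0] / 2.0, shape[1] / 2.0), "radius_nm": model.bead_radius}]
    rng = np.random.default_rng(seed)
    true_z = reported * stage.axial_scale_factor

    frames = np.empty((reported.size,) + shape, dtype=float)
    for i, z in enumerate(true_z):
        img = np.full(shape, model.background, dtype=float)
        for b in beads:
            render_bead(
                model, z - b["radius_nm"], shape, b["center_px"], radius=b["radius_nm"], out=img
            )
        if impurity is not None:
            render_impurity(
                model, z, shape, impurity["center_px"],
                amplitude=impurity.get("amplitude", 400.0), out=img,
            )
        frames[i] = apply_noise(img, model, rng)

    truth = {
        "axial_scale_factor": stage.axial_scale_factor,
        "glass_surface_true_nm": 0.0,
        "glass_surface_reported_nm": 0.0,
        "beads": [
            {
                "center_px": list(b["center_px"]),
                "radius_nm": b["radius_nm"],
                "center_true_nm": b["radius_nm"],
                "center_reported_nm": b["radius_nm"] / stage.axial_scale_factor,
            }
            for b in beads
        ],
        "impurity_px": None if impurity is None else list(impurity["center_px"]),
        "pixel_size_nm": model.pixel_size,
    }
    return BeadZStack(frames, reported, pixel_size=model.pixel_size), truth


# ---------------------------------------------------------------------------
# stage traces / scan protocol


def protocol_segments(schedule: ScanSchedule, baseline: float = 0.0, hold_duration: float = 27.0):
    """Expand a scan schedule into (target_nm, duration_s) hold segments.

    Each z-scan visits the scheduled planes in order; between scans the stage
    parks at the baseline plane for the programmed inter-scan delay.
    """
    segments = []
    for i in range(schedule.n_scans):
        for off in schedule.plane_offsets:
            segments.append((baseline + off, hold_duration))
        if i < schedule.n_scans - 1 and schedule.inter_scan_delay > 0:
            segments.append((baseline, schedule.inter_scan_delay))
    return segments


def simulate_protocol(
    stage: StageModel,
    segments,
    seed: int,
    estimator=None,
    controller_on: bool = True,
    deadband: float = 5.0,
    update_interval: float = 1.0,
    start_position: float | None = None,
):
    """Core stage/drift/backlash timeline shared by trace generation and the
    image-based tracking experiment.

    ``estimator`` maps the true focal position (nm) and an RNG to a measured
    position; None means an ideal (noise-free) readout.  Commanded moves are
    in calibrated nm and realize exactly except for backlash undershoot on
    direction reversal; drift acts on the true position every update.

    Returns a DataFrame with columns t_s, target_nm, measured_nm, stage_nm,
    delta_gp_nm, phase, true_nm.
    """
    rng = np.random.default_rng(seed)
    if estimator is None:
        estimator = lambda z, _rng: z  # noqa: E731 - ideal readout
    segments = list(segments)
    if not segments:
        raise ValueError("empty protocol")

    z_true = segments[0][0] if start_position is None else float(start_position)
    z_stage = 0.0
    settle_updates = max(0, int(round(stage.settle_time / update_interval)))
    dt = update_interval
    sqrt_dt = np.sqrt(dt)

    # Backlash as drive-train play: ``play`` is the engagement position within
    # the gap, in [0, backlash].  A move first takes up remaining play in its
    # direction, so the first move after a reversal undershoots by up to the
    # full backlash, while repeated small same-direction moves ratchet the
    # drive back into engagement.  The drive starts engaged in the direction
    # of the first commanded move.
    play = None

    def move(delta: float) -> None:
        nonlocal z_true, z_stage, play
        if delta == 0.0:
            return
        if play is None:
            play = stage.backlash if delta > 0 else 0.0
        if delta > 0:
            realized = max(0.0, delta - (stage.backlash - play))
            play = min(stage.backlash, play + delta)
        else:
            realized = -max(0.0, -delta - play)
            play = max(0.0, play + delta)
        z_true += realized
        z_stage += delta

    rows = []
    t = 0.0
    measured = estimator(z_true, rng)
    bead_lost = False
    for target, duration in segments:
        # commanded move to the new target: closed loop commands from the live
        # estimate, open loop blindly target-to-target
        move(target - measured if controller_on else target - _last_target(rows, target))
        n_updates = max(1, int(round(duration / dt)))
        for k in range(n_updates):
            z_true += stage.drift_rate * dt + rng.normal(0.0, stage.drift_random_walk_sd * sqrt_dt)
            try:
                measured = estimator(z_true, rng)
            except BeadLostError:
                bead_lost = True
                break
            delta_gp = measured - target
            phase = "moving" if k < settle_updates else "holding"
            rows.append((t, target, measured, z_stage, delta_gp, phase, z_true))
            # the loop corrects in real time, during settling as well as holds
            if controller_on and abs(delta_gp) > deadband:
                move(-delta_gp)
            t += dt
        if bead_lost:
            break
    trace = pd.DataFrame(
        rows,
        columns=["t_s", "target_nm", "measured_nm", "stage_nm", "delta_gp_nm", "phase", "true_nm"],
    )
    trace.attrs["bead_lost"] = bead_lost
    return trace


def _last_target(rows, default):
    return rows[-1][1] if rows else default


def generate_stage_trace(
    stage: StageModel,
    schedule: ScanSchedule,
    controller: str = "on",
    seed: int = 0,
    baseline: float = 0.0,
    hold_duration: float = 27.0,
    deadband: float = 5.0,
    update_interval: float = 1.0,
) -> pd.DataFrame:
    """Simulate the scan protocol with an ideal position readout.

    ``controller`` is "on" (closed loop, corrections beyond the deadband) or
    "off" (open loop: blind target-to-target moves, drift uncompensated).
    """
    if controller not in ("on", "off"):
        raise ValueError("controller must be 'on' or 'off'")
    segments = protocol_segments(schedule, baseline=baseline, hold_duration=hold_duration)
    return simulate_protocol(
        stage,
        segments,
        seed=seed,
        estimator=None,
        controller_on=(controller == "on"),
        deadband=deadband,
        update_interval=update_interval,
    )


# ---------------------------------------------------------------------------
# fluorophore spectra


def fluorophore_spectrum(
    wavelengths, peak: float, sigma_blue: float, sigma_red: float
) -> np.ndarray:
    """Asymmetric (two-sided Gaussian) emission spectrum, normalized to unit sum.

    The red tail is broader than the blue edge, as for GFP-family emitters.
    """
    lam = np.asarray(wavelengths, dtype=float)
    sig = np.where(lam < peak, sigma_blue, sigma_red)
    w = np.exp(-((lam - peak) ** 2) / (2.0 * sig**2))
    return w / w.sum()


def default_spectra(wavelengths) -> dict:
    """mEGFP-like and mCitrine-like elementary emission spectra."""
    return {
        "mEGFP": fluorophore_spectrum(wavelengths, 508.0, 12.0, 35.0),
        "mCitrine": fluorophore_spectrum(wavelengths, 529.0, 13.0, 38.0),
    }


# ---------------------------------------------------------------------------
# cell time series


@dataclass
class CellGroundTruth:
    """Per-time-point truth for a two-fluorophore recruitment time series.

    The membrane cross-profile of each protein is a Gaussian ridge
    f(x) = A exp(-(mu-x)^2 / 2 sigma^2); the arrestin cytoplasmic pool is a
    sigmoid g(x) = L + (U-L)/(1 + (x/C)^B) in the re-indexed profile
    coordinate (x = 1 at the intracellular ROI edge).  Recruitment transfers
    arrestin amplitude from cytoplasm to membrane with a conserved total:
    A_arr(t) sigma_arr sqrt(2 pi) + (U(t) - L) C = const.
    """

    times_min: np.ndarray  # relative to agonist addition
    shape: tuple[int, int] = (188, 128)
    pixel_size: float = 250.0  # nm
    channel_wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(450.0, 600.0, 16)
    )
    mu: int = 80  # aligned membrane column (re-indexed coordinate)
    sigma_receptor: float = 2.0  # px
    sigma_arrestin: float = 2.0  # px
    receptor_amplitude: float = 1060.0  # a.u., constant in time
    arrestin_amplitude0: float = 30.0  # a.u., pre-treatment membrane arrestin
    U0: float = 400.0  # a.u., cytoplasmic plateau before treatment
    L: float = 5.0  # a.u., extracellular plateau
    B: float = 8.0
    C: float = 76.0  # px, sigmoid inflection column
    transfer_max: float = 0.5  # max fraction of cytoplasm pool transferred
    tau_min: float = 18.0  # recruitment time constant
    curvature: float = 0.0011  # px shift per row^2 (membrane bowing)
    spectra: dict | None = None
    epsilon: dict = field(default_factory=lambda: {"mEGFP": 50.0, "mCitrine": 40.0})
    area_factor_um2: float = 0.2121  # PSF^2 area factor used for unit bookkeeping
    vesicle: dict | None = None  # {"row": r, "col_offset": d, "amplitude": a}
    n_puncta: int = 8
    n_shared_puncta: int = 5

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.spectra is None:
            self.spectra = default_spectra(self.channel_wavelengths)
        for w in self.spectra.values():
            if np.any(np.asarray(w) < 0) or abs(float(np.sum(w)) - 1.0) > 1e-9:
                raise ValueError("elementary spectra must be nonnegative and sum to 1")

    @classmethod
    def default(cls, n_timepoints: int = 14, interval_s: float = 300.0, **kw) -> "CellGroundTruth":
        """The standard recruitment protocol: two untreated scans, agonist at
        t = 0, then scans every ``interval_s`` for the remainder."""
        if n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        times = (np.arange(n_timepoints) - 2) * interval_s / 60.0
        return cls(times_min=times, **kw)

    # -- kinetics ----------------------------------------------------------
    def transfer_fraction(self, t_min: float) -> float:
        if t_min < 0:
            return 0.0
        return self.transfer_max * (1.0 - np.exp(-t_min / self.tau_min))

    def arrestin_params(self, t_min: float) -> dict:
        """Time-resolved (A, U) with the conserved-total transfer rule."""
        phi = self.transfer_fraction(t_min)
        moved = phi * (self.U0 - self.L) * self.C  # a.u. * px, per row
        U = self.U0 - phi * (self.U0 - self.L)
        A = self.arrestin_amplitude0 + moved / (self.sigma_arrestin * np.sqrt(2.0 * np.pi))
        return {"A": A, "U": U, "L": self.L, "B": self.B, "C": self.C,
                "sigma": self.sigma_arrestin, "mu": self.mu}

    def total_arrestin(self, t_min: float) -> float:
        p = self.arrestin_params(t_min)
        return p["A"] * p["sigma"] * np.sqrt(2.0 * np.pi) + (p["U"] - p["L"]) * p["C"]

    def row_shifts(self) -> np.ndarray:
        """Whole-pixel membrane-column shift per row (parabolic bowing).

        Quantized to integer pixels so that integer re-alignment inverts the
        curvature exactly and noiseless fits recover the truth to numerical
        tolerance.
        """
        r = np.arange(self.shape[0], dtype=float) - self.shape[0] / 2.0
        return np.round(self.curvature * r**2).astype(int)

    def membrane_peak_columns(self) -> np.ndarray:
        return self.mu + self.row_shifts()

    # -- profiles ----------------------------------------------------------
    def receptor_profile(self, x: np.ndarray) -> np.ndarray:
        return self.receptor_amplitude * np.exp(
            -((self.mu - x) ** 2) / (2.0 * self.sigma_receptor**2)
        )

    def arrestin_profile(self, x: np.ndarray, t_min: float) -> np.ndarray:
        p = self.arrestin_params(t_min)
        f = p["A"] * np.exp(-((p["mu"] - x) ** 2) / (2.0 * p["sigma"] ** 2))
        g = p["L"] + (p["U"] - p["L"]) / (1.0 + (x / p["C"]) ** p["B"])
        return f + g

    # -- densities (unit bookkeeping: a.u.*px / (a.u./molecule * um^2)) ----
    def receptor_density(self) -> float:
        ig = self.receptor_amplitude * self.sigma_receptor * np.sqrt(2.0 * np.pi)
        return ig / (self.epsilon["mEGFP"] * self.area_factor_um2)

    def arrestin_density(self, t_min: float) -> float:
        p = self.arrestin_params(t_min)
        ig = p["A"] * p["sigma"] * np.sqrt(2.0 * np.pi)
        return ig / (self.epsilon["mCitrine"] * self.area_factor_um2)

    def to_dict(self) -> dict:
        d = {
            "times_min": self.times_min.tolist(),
            "shape": list(self.shape),
            "mu": self.mu,
            "sigma_receptor": self.sigma_receptor,
            "sigma_arrestin": self.sigma_arrestin,
            "receptor_amplitude": self.receptor_amplitude,
            "U0": self.U0, "L": self.L, "B": self.B, "C": self.C,
            "transfer_max": self.transfer_max, "tau_min": self.tau_min,
            "curvature": self.curvature,
            "row_shifts": self.row_shifts().tolist(),
            "epsilon": self.epsilon,
            "area_factor_um2": self.area_factor_um2,
            "spectra": {k: np.asarray(v).tolist() for k, v in self.spectra.items()},
            "arrestin_A": [self.arrestin_params(t)["A"] for t in self.times_min],
            "arrestin_U": [self.arrestin_params(t)["U"] for t in self.times_min],
            "receptor_density": self.receptor_density(),
            "arrestin_density": [self.arrestin_density(t) for t in self.times_min],
            "total_arrestin": [self.total_arrestin(t) for t in self.times_min],
        }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _compose_stack(
    truth: CellGroundTruth, maps: dict, rng: np.random.Generator, noise: str,
    timestamp: float, plane_label: str,
) -> SpectralStack:
    """Abundance-weighted sum of elementary spectra per pixel, plus shot noise."""
    h, w = truth.shape
    n_ch = truth.channel_wavelengths.size
    cube = np.zeros((h, w, n_ch))
    for label, amap in maps.items():
        cube += amap[:, :, None] * np.asarray(truth.spectra[label])[None, None, :]
    if noise == "poisson":
        cube = rng.poisson(np.clip(cube, 0.0, None)).astype(float)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")
    return SpectralStack(
        cube, truth.channel_wavelengths, pixel_size=truth.pixel_size,
        timestamp=timestamp, plane_label=plane_label,
    )


def _cross_section_maps(truth: CellGroundTruth, t_min: float) -> dict:
    h, w = truth.shape
    shifts = truth.row_shifts()
    x0 = np.arange(1, w + 1, dtype=float)  # re-indexed profile coordinate
    rec = np.empty((h, w))
    arr = np.empty((h, w))
    for r in range(h):
        # shift by evaluation, continuing the cytoplasm plateau leftward
        # (x' clamped positive keeps the sigmoid argument defined)
        x_eval = np.clip(x0 - shifts[r], 0.5, None)
        rec[r] = truth.receptor_profile(x_eval)
        arr[r] = truth.arrestin_profile(x_eval, t_min)
    if truth.vesicle is not None:
        v = truth.vesicle
        rr = np.arange(h)[:, None] - v["row"]
        cc = np.arange(w)[None, :] - (truth.mu + shifts[v["row"]] + v["col_offset"])
        rec += v["amplitude"] * np.exp(-(rr**2 + cc**2) / (2.0 * 1.5**2))
    return {"mEGFP": rec, "mCitrine": arr}


def _basolateral_maps(truth: CellGroundTruth, t_min: float, rng: np.random.Generator,
                      punctum_xy: np.ndarray) -> dict:
    h, w = truth.shape
    phi = truth.transfer_fraction(t_min)
    rec = np.full((h, w), 600.0)
    arr = np.full((h, w), 50.0)
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    for i, (pr, pc) in enumerate(punctum_xy):
        blob = np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * 1.5**2))
        rec += 500.0 * phi * blob
        if i < truth.n_shared_puncta:
            arr += 400.0 * phi * blob
    return {"mEGFP": rec, "mCitrine": arr}


def generate_cell_timeseries(
    truth: CellGroundTruth | None = None,
    n_timepoints: int = 14,
    interval: float = 300.0,
    seed: int = 0,
    noise: str = "poisson",
):
    """Generate the two-plane recruitment time series.

    Returns ``(pairs, truth)`` where ``pairs`` is a list of
    ``(basolateral, cross_section)`` SpectralStack tuples, one per z-scan.
    """
    if truth is None:
        truth = CellGroundTruth.default(n_timepoints=n_timepoints, interval_s=interval)
    if truth.times_min.size < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    mr, mc = min(10, h // 4), min(10, w // 4)
    punctum_xy = np.column_stack([
        rng.uniform(mr, h - mr, truth.n_puncta),
        rng.uniform(mc, w - mc, truth.n_puncta),
    ])
    pairs = []
    for t_min in truth.times_min:
        ts = float(t_min) * 60.0
        baso = _compose_stack(
            truth, _basolateral_maps(truth, t_min, rng, punctum_xy), rng, noise,
            timestamp=ts, plane_label="basolateral",
        )
        cross = _compose_stack(
            truth, _cross_section_maps(truth, t_min), rng, noise,
            timestamp=ts, plane_label="+2.34 um",
        )
        pairs.append((baso, cross))
    return pairs, truth


# ---------------------------------------------------------------------------
# dilution series (brightness calibration input)


def generate_dilution_series(
    epsilon_true: float,
    volume_integral_um3: float,
    concentrations_uM=(7.7, 3.8, 1.9, 1.0, 0.5),
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "mEGFP",
):
    """Mean solution intensities at the standard concentration ladder.

    Built so that the dilution-series slope Theta (a.u. per number density)
    times the PSF^2 volume integral returns ``epsilon_true`` exactly in the
    noiseless case.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations_uM, dtype=float)
    rho = c * AVOGADRO_PER_UM3_PER_UM  # molecules / um^3
    intensities = epsilon_true * rho / volume_integral_um3
    if noise_sd > 0:
        intensities = intensities + rng.normal(0.0, noise_sd, size=c.size)
    return c, intensities, label
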
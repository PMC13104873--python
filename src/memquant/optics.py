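"""Optical forward models: bead reflected-light rendering and the excitation
point-spread function.

The reflected-light appearance of a micron-scale bead is modeled as a bright
rim whose radius follows the spherical cross-section,

    r(dz) = sqrt(R^2 - dz^2)            for |dz| <= R,
    r(dz) = cone_slope * (|dz| - R)     for |dz| >  R  (defocus cone),

where dz is the true focal-plane offset from the bead center.  The rim is a
radial Gaussian of constant thickness (optionally growing symmetrically with
defocus via ``blur_waist``) whose amplitude decays with defocus.  Within the
bead the appearance is symmetric about the equator, which is what the width
calibration exploits; on the defocus cone beyond the bead the ring radius is
strictly monotone in dz, which is what template-based focal lookup exploits
(libraries are recorded on one side of the bead).  This image-formation
model is a stand-in (the real contrast mechanism of reflected LED
illumination is not modeled) and is isolated here so it can be swapped.

The excitation PSF is a 3D Gaussian, PSF(x,y,z) = exp(-2(x^2+y^2)/w0^2
- 2 z^2/wz^2), amplitude 1 at the origin, which admits closed-form checks of
the squared-PSF integrals used for brightness normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class OpticalModel:
    """Parameters of the image-formation stand-in.

    Waists are 1/e^2 Gaussian beam waists in nm.  ``noise`` is one of
    ``none``, ``poisson``, ``gaussian`` (with ``gaussian_sigma`` counts).
    """

    lateral_waist: float = 300.0  # w0, nm
    axial_waist: float = 900.0  # wz, nm
    bead_radius: float = 1875.0  # nm
    background: float = 20.0  # a.u. (counts)
    peak_amplitude: float = 1000.0  # a.u.
    noise: str = "poisson"
    gaussian_sigma: float = 5.0  # a.u., for noise="gaussian"
    pixel_size: float = 250.0  # nm per pixel
    # bead-appearance shape parameters
    rim_sigma_px: float = 1.0  # rim thickness, px
    cone_slope: float = 0.7  # apparent ring growth per nm of defocus beyond R
    blur_waist: float | None = None  # nm; None = constant rim thickness
    amp_waist: float = 2500.0  # nm, axial scale of amplitude decay

    def __post_init__(self) -> None:
        if self.lateral_waist <= 0 or self.axial_waist <= 0 or self.bead_radius <= 0:
            raise ValueError("waists and bead radius must be positive")
        if self.noise not in ("none", "poisson", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")


def bead_rim_radius(dz: float, radius: float, cone_slope: float) -> float:
    """Apparent bright-rim radius (nm) at true defocus ``dz`` from the center."""
    if abs(dz) <= radius:
        return float(np.sqrt(radius**2 - dz**2))
    return float(cone_slope * (abs(dz) - radius))


def render_bead(
    model: OpticalModel,
    dz: float,
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float | None = None,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Render (add) one bead at focal offset ``dz`` (nm, true) into an image.

    ``center`` is the (row, col) bead axis position in px.  Background is NOT
    added here (scene-level).
    """
    R = model.bead_radius if radius is None else radius
    r_px = bead_rim_radius(dz, R, model.cone_slope) / model.pixel_size
    s_px = model.rim_sigma_px
    if model.blur_waist is not None:
        s_px = s_px * np.sqrt(1.0 + (dz / model.blur_waist) ** 2)
    amp = model.peak_amplitude / (1.0 + (dz / model.amp_waist) ** 2)
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    rho = np.hypot(rows, cols)
    img = amp * np.exp(-((rho - r_px) ** 2) / (2.0 * s_px**2))
    if out is None:
        return img
    out += img
    return out


def render_impurity(
    model: OpticalModel,
    z_true: float,
    shape: tuple[int, int],
    center: tuple[float, float],
    amplitude: float = 400.0,
    sigma0_px: float = 1.2,
    axial_scale: float = 500.0,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Render a sub-diffraction glass-surface impurity as a diffraction-limited
    Gaussian spot.  Amplitude is maximal when the true focal plane is at the
    glass surface (z_true = 0) and decays with defocus while the spot widens."""
    scale = 1.0 + (z_true / axial_scale) ** 2
    amp = amplitude / scale
    s_px = sigma0_px * np.sqrt(scale)
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    img = amp * np.exp(-(rows**2 + cols**2) / (2.0 * s_px**2))
    if out is None:
        return img
    out += img
    return out


def apply_noise(img: np.ndarray, model: OpticalModel, rng: np.random.Generator) -> np.ndarray:
    """Apply the model's noise to an expected-counts image."""
    if model.noise == "none":
        return img
    if model.noise == "poisson":
        return rng.poisson(np.clip(img, 0.0, None)).astype(float)
    return img + rng.normal(0.0, model.gaussian_sigma, size=img.shape)


def gaussian_psf_squared(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, w0: float, wz: float
) -> np.ndarray:
    """PSF^2 of the Gaussian excitation model on broadcastable coordinates (nm)."""
    return np.exp(-4.0 * (x**2 + y**2) / w0**2 - 4.0 * z**2 / wz**2)
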
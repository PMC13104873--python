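"""Monomeric fluorophore brightness from a dilution series, and the numerical
squared-PSF integrals used to normalize intensities to concentrations.

Purified fluorophore solutions imaged at several known concentrations give a
linear intensity-versus-concentration relation whose slope Theta, multiplied
by the squared-PSF volume integral, yields the per-molecule brightness
epsilon_proto.  The micromolar-to-number-density conversion is applied here
so epsilon carries per-molecule units.  For the Gaussian excitation PSF the
integrals have closed forms (volume: pi^(3/2) w0^2 wz / 8; area factor over
the x = 0 plane: pi w0 wz / 4), which serve as convergence references for
the trapezoidal quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .optics import OpticalModel
from .simulate import AVOGADRO_PER_UM3_PER_UM


@dataclass
class DilutionSeries:
    """Mean solution intensities (a.u.) at known concentrations (uM)."""

    concentrations: np.ndarray
    intensities: np.ndarray
    fluorophore_label: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentrations.size != self.intensities.size or self.concentrations.size < 3:
            raise ValueError("need >= 3 matched concentration/intensity points")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class PsfIntegrals:
    """Numerical integrals of the squared PSF: the excitation volume
    (nm^3 or um^3, per ``units``) and the area factor over the plane through
    the focus (nm^2 or um^2)."""

    volume_integral: float
    area_factor: float
    w0: float
    wz: float
    units: str = "nm"

    def __post_init__(self) -> None:
        if self.volume_integral <= 0 or self.area_factor <= 0:
            raise ValueError("integrals must be positive")

    def to_um(self) -> "PsfIntegrals":
        if self.units == "um":
            return self
        return PsfIntegrals(
            self.volume_integral * 1e-9, self.area_factor * 1e-6,
            self.w0, self.wz, units="um",
        )


def fit_slope(series: DilutionSeries) -> dict:
    """Ordinary least-squares line through the dilution series.

    Returns slope Theta (a.u. per uM), intercept, and R^2.
    """
    if np.all(series.concentrations == series.concentrations[0]):
        raise ValueError("all concentrations identical; slope undefined")
    fit = linregress(series.concentrations, series.intensities)
    return {
        "theta": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "fluorophore_label": series.fluorophore_label,
    }


def psf_squared_integrals(
    psf: OpticalModel,
    extent_waists: float = 5.0,
    n_points: int = 201,
    refine_tol: float = 1e-3,
    max_refinements: int = 4,
) -> PsfIntegrals:
    """Trapezoidal quadrature of PSF^2 over 3D (volume integral) and over the
    x = 0 plane (area factor), on a uniform grid extending ``extent_waists``
    waists per axis, refined by grid halving until both results change by
    less than ``refine_tol`` (relative).  Emits a precision warning if the
    tolerance is not reached.
    """
    if extent_waists < 4.0:
        raise ValueError("grid must extend >= 4 waists per axis")
    w0, wz = psf.lateral_waist, psf.axial_waist

    def compute(n: int) -> tuple[float, float]:
        x = np.linspace(-extent_waists * w0, extent_waists * w0, n)
        z = np.linspace(-extent_waists * wz, extent_waists * wz, n)
        gx = np.exp(-4.0 * x**2 / w0**2)
        gz = np.exp(-4.0 * z**2 / wz**2)
        ix = np.trapezoid(gx, x)
        iz = np.trapezoid(gz, z)
        # PSF^2 separates: volume = Ix * Iy * Iz with Iy = Ix; area = Iy * Iz
        return ix * ix * iz, ix * iz

    vol, area = compute(n_points)
    n = n_points
    for _ in range(max_refinements):
        n = 2 * n - 1
        vol2, area2 = compute(n)
        if abs(vol2 - vol) < refine_tol * vol and abs(area2 - area) < refine_tol * area:
            vol, area = vol2, area2
            break
        vol, area = vol2, area2
    else:
        warnings.warn("PSF^2 quadrature did not reach the requested precision",
                      RuntimeWarning, stacklevel=2)
    return PsfIntegrals(vol, area, w0=w0, wz=wz, units="nm")


def gaussian_psf_closed_forms(w0: float, wz: float) -> tuple[float, float]:
    """Closed-form (volume, area-factor) integrals of the squared Gaussian
    PSF: pi^(3/2) w0^2 wz / 8 and pi w0 wz / 4."""
    return float(np.pi**1.5 * w0**2 * wz / 8.0), float(np.pi * w0 * wz / 4.0)


def epsilon_proto(theta: float, integrals: PsfIntegrals) -> dict:
    """Monomeric brightness: the dilution slope (converted from per-uM to per
    number density, molecules/um^3) times the squared-PSF volume integral.

    Returns the brightness with its unit bookkeeping.
    """
    integ = integrals.to_um()
    theta_density = theta / AVOGADRO_PER_UM3_PER_UM  # a.u. per (molecule/um^3)
    eps = theta_density * integ.volume_integral
    return {
        "epsilon_proto": float(eps),
        "units": "a.u. per molecule",
        "theta_au_per_uM": float(theta),
        "theta_au_per_molecule_per_um3": float(theta_density),
        "psf_volume_integral_um3": float(integ.volume_integral),
        "psf_area_factor_um2": float(integ.area_factor),
        "area_factor_note": (
            "area factor is the 2D integral of PSF^2 over the x=0 plane"
        ),
    }
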
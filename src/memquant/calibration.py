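"""Axial stage calibration from reflected-light bead z-stacks.

The motorized objective stage of an inverted microscope under-reports true
focal displacement (refractive-index mismatch, drive-train geometry).  The
calibration factor — true focal displacement per reported displacement — is
measured from spherical beads of known radius adsorbed to the coverslip:

* Method 1 (glass-to-center): the reported displacement between the glass
  surface (located via a sub-diffraction surface impurity) and a bead's
  equatorial plane is compared to the manufacturer bead radius.
* Method 2 (center-to-center): the reported displacement between the
  equatorial planes of two differently sized beads is compared to the known
  difference of their radii.

The equatorial plane of a bead is found as the maximum of its apparent width
versus reported position; the width of each frame is the peak-to-peak
separation 2d of a symmetric double-Gaussian fit to the intensity profile
through the bead center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .types import BeadZStack


@dataclass
class BeadWidthCurve:
    """Apparent bead width (px) versus reported objective position (nm)."""

    reported_position: np.ndarray
    width: np.ndarray
    fit_quality: np.ndarray  # residual norm per sample; NaN width = flagged

    def __post_init__(self) -> None:
        self.reported_position = np.asarray(self.reported_position, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        self.fit_quality = np.asarray(self.fit_quality, dtype=float)
        if not (len(self.reported_position) == len(self.width) == len(self.fit_quality)):
            raise ValueError("curve arrays must have equal length")
        if np.any(self.width[np.isfinite(self.width)] < 0):
            raise ValueError("widths must be nonnegative")


@dataclass
class CalibrationResult:
    """Axial calibration factor and the measurements behind it."""

    factor: float
    method: str  # "glass_to_center" | "center_to_center"
    surface_plane: float | None = None  # nm reported
    center_planes: list = field(default_factory=list)  # nm reported
    bead_radii_used: list = field(default_factory=list)  # nm

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("calibration factor must be > 0")


def _double_gaussian(x, bg, a, c, d, s):
    return bg + a * (
        np.exp(-((x - c + d) ** 2) / (2.0 * s**2))
        + np.exp(-((x - c - d) ** 2) / (2.0 * s**2))
    )


def fit_bead_width(profile) -> tuple[float, float]:
    """Width (px) of one center-line intensity profile.

    Fits the symmetric double Gaussian bg + a[G(x-c+d) + G(x-c-d)] with shared
    amplitude and width and returns the peak-to-peak separation 2d.  A fit
    that fails to converge (or a featureless profile) yields (nan, residual)
    rather than raising, so a single bad frame never aborts a stack.
    """
    y = np.asarray(profile, dtype=float)
    if y.size < 7:
        raise ValueError("profile too short (need >= 7 samples)")
    x = np.arange(y.size, dtype=float)
    bg0 = float(np.percentile(y, 10))
    span = float(y.max() - bg0)
    if span <= 0 or not np.isfinite(span):
        return np.nan, float(np.linalg.norm(y - y.mean()))
    # moment-based initial guesses: centroid and half-width at half maximum
    w = np.clip(y - bg0, 0.0, None)
    c0 = float((x * w).sum() / w.sum())
    above = np.nonzero(y - bg0 > span / 2.0)[0]
    d0 = max(0.5 * (above[-1] - above[0]), 1.0) if above.size else 2.0
    s0 = max(d0 / 3.0, 0.8)
    try:
        popt, _ = curve_fit(
            _double_gaussian, x, y,
            p0=[bg0, span / 2.0, c0, d0, s0],
            bounds=([-np.inf, 0.0, 0.0, 0.0, 0.1], [np.inf, np.inf, y.size, y.size, y.size]),
            maxfev=5000,
        )
    except RuntimeError:
        return np.nan, float(np.linalg.norm(y - y.mean()))
    resid = float(np.linalg.norm(y - _double_gaussian(x, *popt)))
    width = 2.0 * popt[3]
    # a degenerate merged fit (d ~ 0 with huge s) means no resolvable rim
    if width < 0.2:
        width = 0.0
    return width, resid


def extract_width_curve(stack: BeadZStack, roi) -> BeadWidthCurve:
    """Per-frame bead width from horizontal and vertical center-line profiles.

    ``roi`` is (row, col, height, width) of a bead-centered window.  The two
    profiles are fitted independently and averaged; disagreement beyond 2 px
    flags the frame (NaN width).
    """
    r0, c0, h, w = roi
    n_rows, n_cols = stack.frames.shape[1:]
    if r0 < 0 or c0 < 0 or r0 + h > n_rows or c0 + w > n_cols:
        raise ValueError("ROI outside frame bounds")
    cr, cc = r0 + h // 2, c0 + w // 2
    widths = np.empty(stack.n_frames)
    quality = np.empty(stack.n_frames)
    for i in range(stack.n_frames):
        frame = stack.frames[i]
        wh, qh = fit_bead_width(frame[cr, c0:c0 + w])
        wv, qv = fit_bead_width(frame[r0:r0 + h, cc])
        quality[i] = np.hypot(qh, qv)
        if np.isnan(wh) or np.isnan(wv) or abs(wh - wv) > 2.0:
            widths[i] = np.nan
        else:
            widths[i] = 0.5 * (wh + wv)
    return BeadWidthCurve(stack.reported_positions, widths, quality)


def _parabolic_peak(x: np.ndarray, y: np.ndarray, window: int = 10) -> float:
    """Peak abscissa by least-squares parabola around the argmax.

    ``window`` is the half-width in samples; window=1 is the classic 3-point
    parabolic interpolation.  NaN samples inside the window are skipped.
    """
    valid = np.isfinite(y)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid samples")
    xv, yv = x[valid], y[valid]
    j = int(np.argmax(yv))
    if j == 0 or j == yv.size - 1:
        raise ValueError("maximum at curve edge: scan range does not bracket the peak")
    lo, hi = max(0, j - window), min(yv.size, j + window + 1)
    coef = np.polyfit(xv[lo:hi], yv[lo:hi], 2)
    if coef[0] >= 0:  # not concave; fall back to the raw argmax
        return float(xv[j])
    peak = -coef[1] / (2.0 * coef[0])
    # never extrapolate beyond the fit window
    return float(np.clip(peak, xv[lo], xv[hi - 1]))


def locate_bead_center(curve: BeadWidthCurve, rim_fraction: float = 0.5) -> float:
    """Reported position (nm) of the bead's equatorial plane.

    For a spherical bead the squared width is exactly quadratic in axial
    position, w(z)^2 = 4 (R^2 - k^2 (z - c)^2), so the equator is found as
    the vertex of a least-squares parabola through w^2 over the rim region
    (samples with w above ``rim_fraction`` of the maximum).  This is the
    parabolic refinement of the width-curve maximum, using the whole rim
    rather than the locally flat top, where single-sample noise dominates.
    """
    valid = np.isfinite(curve.width)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid width samples")
    p, w = curve.reported_position[valid], curve.width[valid]
    j = int(np.argmax(w))
    if j == 0 or j == w.size - 1:
        raise ValueError("width maximum at curve edge: scan range does not bracket the center")
    sel = w >= rim_fraction * w[j]
    if sel.sum() < 3:
        raise ValueError("too few rim samples for refinement")
    coef = np.polyfit(p[sel], w[sel] ** 2, 2)
    if coef[0] >= 0:  # not concave; fall back to a local parabola on w itself
        return _parabolic_peak(p, w, window=10)
    vertex = -coef[1] / (2.0 * coef[0])
    return float(np.clip(vertex, p[sel].min(), p[sel].max()))


def _gauss2d(xy, amp, r, c, s, off):
    rr, cc = xy
    return (off + amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * s**2))).ravel()


def locate_glass_surface(stack: BeadZStack, impurity_roi, window: int = 10) -> float:
    """Reported position (nm) of the glass surface from a sub-diffraction
    surface impurity: per frame a 2D Gaussian (amplitude, center, isotropic
    width, offset) is fitted inside ``impurity_roi``; the surface is the
    position of maximum fitted amplitude, parabola-refined."""
    r0, c0, h, w = impurity_roi
    rr, cc = np.mgrid[0:h, 0:w]
    amps = np.full(stack.n_frames, np.nan)
    for i in range(stack.n_frames):
        patch = stack.frames[i, r0:r0 + h, c0:c0 + w]
        off0 = float(np.median(patch))
        amp0 = float(patch.max() - off0)
        pk = np.unravel_index(np.argmax(patch), patch.shape)
        try:
            popt, _ = curve_fit(
                _gauss2d, (rr, cc), patch.ravel(),
                p0=[max(amp0, 1e-3), pk[0], pk[1], 1.5, off0],
                bounds=([0, -1, -1, 0.3, -np.inf], [np.inf, h, w, max(h, w), np.inf]),
                maxfev=2000,
            )
            amps[i] = popt[0]
        except RuntimeError:
            continue
    if not np.any(np.isfinite(amps)):
        raise RuntimeError("no impurity fit converged in any frame")
    finite = amps[np.isfinite(amps)]
    if finite.max() - finite.min() < 1e-6 * max(finite.max(), 1.0):
        raise ValueError("impurity amplitude curve is flat; surface not bracketed")
    return _parabolic_peak(stack.reported_positions, amps, window=window)


def calibration_method1(surface: float, center: float, bead_radius: float) -> CalibrationResult:
    """Glass-to-center method: factor = R / |center - surface| (reported nm)."""
    if bead_radius <= 0:
        raise ValueError("bead radius must be positive")
    disp = abs(center - surface)
    if disp == 0:
        raise ValueError("zero reported displacement between surface and bead center")
    return CalibrationResult(
        factor=bead_radius / disp,
        method="glass_to_center",
        surface_plane=surface,
        center_planes=[center],
        bead_radii_used=[bead_radius],
    )


def calibration_method2(
    center_a: float, center_b: float, radius_a: float, radius_b: float
) -> CalibrationResult:
    """Two-bead method: factor = |Ra - Rb| / |center_a - center_b| (reported nm)."""
    if radius_a == radius_b:
        raise ValueError("bead radii must differ for the two-bead method")
    disp = abs(center_a - center_b)
    if disp == 0:
        raise ValueError("bead centers coincide")
    return CalibrationResult(
        factor=abs(radius_a - radius_b) / disp,
        method="center_to_center",
        center_planes=[center_a, center_b],
        bead_radii_used=[radius_a, radius_b],
    )


def apply_calibration(reported: float, factor: float):
    """Correct a reported displacement (nm) to a true displacement (nm).

    Applies to displacements (differences), not absolute coordinates.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    return np.asarray(reported, dtype=float) * factor if np.ndim(reported) else reported * factor
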
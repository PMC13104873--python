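"""Curvature-corrected membrane cross-section profiles and their models.

A rectangular ROI spanning cytoplasm -> membrane -> extracellular space is
straightened by shifting each row so the membrane intensity peak (found in
the receptor channel) falls in a single column; the same shifts are applied
to the arrestin channel to preserve spatial correspondence.  Column means
give a 1D profile I(x) in the re-indexed coordinate x = 1, 2, ... starting at
the ROI's intracellular edge (so the sigmoid argument (x/C)^B is always
positive; this convention is recorded in every fit).

Models:
    membrane ridge   f(x) = A exp(-(mu - x)^2 / 2 sigma^2)
    cytoplasm pool   g(x) = L + (U - L) / (1 + (x/C)^B)

The receptor profile is fitted with f alone (mu fixed, A and sigma free); the
arrestin profile with f + g (mu fixed; C free on untreated frames, then fixed
to the untreated average for the rest of the series).  The membrane signal is
the Gaussian integral I_Gauss = A sigma sqrt(2 pi), converted to an effective
membrane concentration by dividing by the fluorophore's monomeric brightness
and the squared-PSF area factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.optimize import least_squares

SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass
class AlignmentMatrix:
    """Per-row column shifts that straighten the membrane, the aligned
    membrane column, and the rows excluded from averaging (with reasons)."""

    shifts: np.ndarray  # int px, one per row; applying them puts peaks at mu
    mu: int  # aligned membrane column (re-indexed coordinate, 1-based)
    peak_columns: np.ndarray  # detected per-row peak (0-based col index)
    excluded_rows: dict = field(default_factory=dict)  # row -> reason

    @property
    def included(self) -> np.ndarray:
        mask = np.ones(self.shifts.size, dtype=bool)
        for r in self.excluded_rows:
            mask[r] = False
        return mask


@dataclass
class Profile:
    """Column-mean intensity profile; ``x`` is 1-based from the intracellular
    ROI edge.  Columns with no valid pixels are NaN with n_rows = 0."""

    x: np.ndarray
    mean_intensity: np.ndarray
    n_rows: np.ndarray


@dataclass
class ProfileFit:
    """Fitted profile-model parameters.  ``model`` is "gaussian" (receptor)
    or "gaussian+sigmoid" (arrestin); sigmoid fields are NaN for the former.
    ``mu`` is held fixed during fitting.  ``flags`` records soft anomalies
    (e.g. "U<L")."""

    A: float
    mu: float
    sigma: float
    L: float = float("nan")
    U: float = float("nan")
    B: float = float("nan")
    C: float = float("nan")
    model: str = "gaussian"
    residual_norm: float = float("nan")
    flags: tuple = ()


@dataclass
class ConcentrationPoint:
    """Membrane-associated concentration of one protein at one time point.

    ``concentration`` = I_Gauss / (epsilon_proto * area_factor); units follow
    the inputs (a.u.*px over a.u./molecule * um^2) and are relative unless
    the brightness and area factor carry absolute units.
    """

    time: float  # min relative to treatment
    I_gauss: float  # a.u. * px
    concentration: float
    protein_label: str = ""


# ---------------------------------------------------------------------------
# alignment


def build_alignment(
    region: np.ndarray,
    manual_exclude=(),
    deviation_px: float = 3.0,
    peak_factor: float = 3.0,
    median_window: int = 5,
) -> AlignmentMatrix:
    """Locate the membrane peak in every row of a receptor-channel ROI and
    derive the shifts that align all peaks into one column.

    A row is auto-excluded when its peak column deviates from the rolling
    median of neighboring rows by more than ``deviation_px`` or its peak
    intensity exceeds ``peak_factor`` times the median row peak (vesicle /
    endocytic-structure signature); ``manual_exclude`` adds explicit rows.
    Excluded rows keep their shifts but are flagged.  The aligned column mu is
    the median of included rows' peaks (ties toward the lower column),
    reported 1-based.
    """
    region = np.asarray(region, dtype=float)
    n_rows, width = region.shape
    if width < 9:
        raise ValueError("ROI must span >= 9 columns (cytoplasm to extracellular)")
    peaks = np.argmax(region, axis=1)
    peak_vals = region[np.arange(n_rows), peaks]

    excluded: dict = {int(r): "manual" for r in manual_exclude}
    rolling = median_filter(peaks.astype(float), size=median_window, mode="nearest")
    dev = np.abs(peaks - rolling) > deviation_px
    bright = peak_vals > peak_factor * np.median(peak_vals)
    for r in np.nonzero(dev)[0]:
        excluded.setdefault(int(r), "peak deviates from rolling median")
    for r in np.nonzero(bright)[0]:
        excluded.setdefault(int(r), "peak intensity above vesicle threshold")

    included = np.ones(n_rows, dtype=bool)
    for r in excluded:
        included[r] = False
    if not included.any():
        raise ValueError("all rows excluded")
    med = np.median(peaks[included])
    mu0 = int(np.floor(med))  # ties toward the lower column (0-based here)
    shifts = mu0 - peaks
    return AlignmentMatrix(
        shifts=shifts, mu=mu0 + 1, peak_columns=peaks, excluded_rows=excluded
    )


def apply_alignment(region: np.ndarray, alignment: AlignmentMatrix) -> np.ndarray:
    """Shift each row by its alignment shift; pixels shifted out of the ROI
    are dropped and vacated pixels are NaN (never wrapped)."""
    region = np.asarray(region, dtype=float)
    if region.shape[0] != alignment.shifts.size:
        raise ValueError("region row count differs from the alignment's source")
    out = np.full(region.shape, np.nan)
    width = region.shape[1]
    for r, s in enumerate(alignment.shifts):
        if s >= 0:
            out[r, s:width] = region[r, : width - s]
        else:
            out[r, : width + s] = region[r, -s:]
    return out


def column_profile(aligned: np.ndarray, included_rows=None) -> Profile:
    """Column-wise arithmetic mean over included rows, ignoring missing
    (NaN) pixels; records the number of rows averaged per column."""
    aligned = np.asarray(aligned, dtype=float)
    if included_rows is not None:
        aligned = aligned[np.asarray(included_rows, dtype=bool)]
    if aligned.shape[0] == 0:
        raise ValueError("no included rows to average")
    n = np.sum(np.isfinite(aligned), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, np.nansum(aligned, axis=0) / np.maximum(n, 1), np.nan)
    x = np.arange(1, aligned.shape[1] + 1, dtype=float)
    return Profile(x=x, mean_intensity=mean, n_rows=n)


# ---------------------------------------------------------------------------
# model fitting


def _gauss(x, A, mu, sigma):
    return A * np.exp(-((mu - x) ** 2) / (2.0 * sigma**2))


def _sigmoid(x, L, U, B, C):
    return L + (U - L) / (1.0 + (x / C) ** B)


def fit_receptor_profile(profile: Profile, mu: float) -> ProfileFit:
    """Fit the membrane Gaussian f(x) with mu held fixed; A and sigma free."""
    x, y = _valid_points(profile)
    if x.size < 5 or not (x.min() < mu < x.max()):
        raise ValueError("need >= 5 valid points spanning the membrane peak")
    A0 = max(float(y.max() - np.percentile(y, 10)), 1e-6)
    res = least_squares(
        lambda p: _gauss(x, p[0], mu, p[1]) - y,
        x0=[A0, 2.0],
        bounds=([0.0, 0.1], [np.inf, x.size]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    if not res.success:
        raise RuntimeError(f"receptor profile fit did not converge: {res.message}")
    flags = ()
    if res.x[0] < 1e-3 * max(y.max(), 1.0):
        flags += ("A~0",)
    if res.x[1] > 0.9 * x.size:  # as wide as the window: no resolvable peak
        flags += ("degenerate",)
    return ProfileFit(
        A=float(res.x[0]), mu=float(mu), sigma=float(res.x[1]),
        model="gaussian", residual_norm=float(np.linalg.norm(res.fun)), flags=flags,
    )


def fit_arrestin_profile(profile: Profile, mu: float, C: float | None = None) -> ProfileFit:
    """Fit f(x) + g(x) with mu fixed; C free when None, else held fixed.

    Initial guesses follow the profile: U from the intracellular tail, L from
    the extracellular tail, A from the peak above the cytoplasm plateau,
    sigma = 2 px, B = 8, C = mu.
    """
    x, y = _valid_points(profile)
    if x.size < 7 or not (x.min() < mu < x.max()):
        raise ValueError("need valid points spanning both plateaus and the peak")
    U0 = float(np.mean(y[:3]))
    L0 = float(np.mean(y[-3:]))
    # inflection guess: first crossing of the plateau midpoint from the left
    mid = 0.5 * (U0 + L0)
    below = np.nonzero(y < mid)[0]
    C0 = float(x[below[0]]) if below.size else float(mu)
    # peak amplitude above the local sigmoid estimate at the membrane column
    g0_at_mu = L0 + (U0 - L0) / (1.0 + (mu / C0) ** 8.0)
    near = np.abs(x - mu) <= 2
    A0 = max(float(y[near].max() - g0_at_mu) if near.any() else 1e-6, 1e-6)
    fixed_C = C is not None

    if fixed_C:
        def residual(p):
            return _gauss(x, p[0], mu, p[1]) + _sigmoid(x, p[2], p[3], p[4], C) - y
        x0 = [A0, 2.0, L0, U0, 8.0]
        lb = [0.0, 0.1, 0.0, 0.0, 0.5]
        ub = [np.inf, x.size, np.inf, np.inf, 60.0]
    else:
        def residual(p):
            return _gauss(x, p[0], mu, p[1]) + _sigmoid(x, p[2], p[3], p[4], p[5]) - y
        x0 = [A0, 2.0, L0, U0, 8.0, C0]
        lb = [0.0, 0.1, 0.0, 0.0, 0.5, 1.0]
        ub = [np.inf, x.size, np.inf, np.inf, 60.0, float(x.max())]

    res = least_squares(residual, x0=x0, bounds=(lb, ub),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000)
    if not res.success:
        raise RuntimeError(f"arrestin profile fit did not converge: {res.message}")
    L, U, B = res.x[2], res.x[3], res.x[4]
    flags = ("U<L",) if U < L else ()
    return ProfileFit(
        A=float(res.x[0]), mu=float(mu), sigma=float(res.x[1]),
        L=float(L), U=float(U), B=float(B),
        C=float(C) if fixed_C else float(res.x[5]),
        model="gaussian+sigmoid",
        residual_norm=float(np.linalg.norm(res.fun)), flags=flags,
    )


def _valid_points(profile: Profile):
    m = np.isfinite(profile.mean_intensity)
    return profile.x[m], profile.mean_intensity[m]


def fix_C_from_untreated(fits) -> float:
    """Average the sigmoid inflection C over untreated (free-C) fits; the
    result is held fixed for every treated frame of the series."""
    fits = list(fits)
    if not fits:
        raise ValueError("no untreated fits supplied")
    return float(np.mean([f.C for f in fits]))


# ---------------------------------------------------------------------------
# integration & concentration


def integrate_gaussian(fit: ProfileFit) -> float:
    """Closed-form Gaussian integral I_Gauss = A sigma sqrt(2 pi)."""
    if not (np.isfinite(fit.A) and np.isfinite(fit.sigma)):
        raise ValueError("fit lacks valid A, sigma")
    return fit.A * fit.sigma * SQRT_2PI


def membrane_concentration(I_gauss: float, epsilon_proto: float, psf_area_factor: float) -> float:
    """Effective membrane concentration: I_Gauss normalized by the monomeric
    brightness and the squared-PSF area factor."""
    if epsilon_proto <= 0 or psf_area_factor <= 0:
        raise ValueError("brightness and area factor must be positive")
    return I_gauss / (epsilon_proto * psf_area_factor)


def arrestin_total_signal(fit: ProfileFit) -> float:
    """Conserved-budget diagnostic: membrane integral plus the cytoplasm pool
    proxy (U - L) * C.  Constant over a series when recruitment merely moves
    arrestin between compartments."""
    if fit.model != "gaussian+sigmoid":
        raise ValueError("total signal is defined for gaussian+sigmoid fits")
    return integrate_gaussian(fit) + (fit.U - fit.L) * fit.C


def concentration_series(
    fits_by_protein: dict,
    epsilon: dict,
    area_factor: float,
    receptor_label: str | None = None,
    arrestin_label: str | None = None,
):
    """Per-time-point membrane concentrations plus trend guides.

    ``fits_by_protein`` maps protein label -> list of (time_min, ProfileFit).
    The receptor series is fitted with an ordinary least-squares line and the
    arrestin series with a third-order polynomial; both are labeled as guides
    to the eye, not kinetic models.

    Returns ``(points, trends)``: a list of :class:`ConcentrationPoint` and a
    dict label -> {"model", "coefficients" (highest degree first), "role"}.
    """
    points = []
    trends = {}
    for label, series in fits_by_protein.items():
        if len(series) < 2:
            raise ValueError("need >= 2 time points per protein")
        times = np.array([t for t, _ in series], dtype=float)
        concs = np.array([
            membrane_concentration(integrate_gaussian(f), epsilon[label], area_factor)
            for _, f in series
        ])
        for t, f, c in zip(times, (f for _, f in series), concs):
            points.append(ConcentrationPoint(
                time=float(t), I_gauss=integrate_gaussian(f),
                concentration=float(c), protein_label=label,
            ))
        if label == arrestin_label:
            deg, role = 3, "arrestin (cubic guide to the eye)"
        else:
            deg, role = 1, "receptor (linear guide to the eye)"
        trends[label] = {
            "model": "cubic" if deg == 3 else "linear",
            "coefficients": np.polyfit(times, concs, deg).tolist(),
            "role": role,
        }
    return points, trends
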
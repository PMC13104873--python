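"""End-to-end recruitment quantification: from spectral cross-section stacks
to membrane-concentration time series.

For each z-scan: unmix the cross-section stack into receptor and arrestin
maps, straighten the membrane using the receptor channel, apply the same
shifts to the arrestin channel, average columns, and fit the profile models.
The sigmoid inflection C is first fitted freely on the untreated scans
(negative times), averaged, and then held fixed for every treated scan.
Gaussian integrals are converted to concentrations with the supplied
brightness values and squared-PSF area factor.
"""

from __future__ import annotations

import numpy as np

from . import profiles as pr
from .types import SpectralStack
from .unmixing import ElementarySpectrum, unmix_stack


def quantify_recruitment(
    scans,
    spectra: dict,
    epsilon: dict,
    area_factor: float,
    receptor_label: str = "mEGFP",
    arrestin_label: str = "mCitrine",
    roi=None,
    nonnegative: bool = True,
) -> dict:
    """Quantify a recruitment time series.

    Parameters
    ----------
    scans : list of (time_min, SpectralStack)
        Cross-section stacks, time relative to agonist addition (untreated
        scans have negative times).
    spectra : dict label -> per-channel weights (elementary spectra).
    epsilon : dict label -> monomeric brightness (a.u./molecule).
    area_factor : squared-PSF area factor (um^2).
    roi : (row, col, height, width) or None for the full frame.

    Returns a dict with per-scan fits, the fixed C, concentration points and
    trend guides, and the arrestin conserved-budget diagnostic.
    """
    elem = [
        ElementarySpectrum(np.asarray(spectra[receptor_label]), receptor_label),
        ElementarySpectrum(np.asarray(spectra[arrestin_label]), arrestin_label),
    ]

    def crop(values: np.ndarray) -> np.ndarray:
        if roi is None:
            return values
        r0, c0, h, w = roi
        return values[r0:r0 + h, c0:c0 + w]

    records = []
    for t_min, stack in scans:
        if not isinstance(stack, SpectralStack):
            raise TypeError("scans must contain SpectralStack objects")
        result = unmix_stack(stack, elem, nonnegative=nonnegative)
        rec = crop(result.abundance[receptor_label].values)
        arr = crop(result.abundance[arrestin_label].values)
        alignment = pr.build_alignment(rec)
        rec_prof = pr.column_profile(pr.apply_alignment(rec, alignment), alignment.included)
        arr_prof = pr.column_profile(pr.apply_alignment(arr, alignment), alignment.included)
        rec_fit = pr.fit_receptor_profile(rec_prof, mu=alignment.mu)
        records.append({
            "time_min": float(t_min),
            "alignment": alignment,
            "receptor_fit": rec_fit,
            "arrestin_profile": arr_prof,
        })

    untreated = [r for r in records if r["time_min"] < 0]
    if not untreated:
        raise ValueError("series contains no untreated (t < 0) scans to fix C")
    free_fits = [
        pr.fit_arrestin_profile(r["arrestin_profile"], mu=r["alignment"].mu)
        for r in untreated
    ]
    fixed_C = pr.fix_C_from_untreated(free_fits)
    for r in records:
        r["arrestin_fit"] = pr.fit_arrestin_profile(
            r["arrestin_profile"], mu=r["alignment"].mu, C=fixed_C
        )

    fits_by_protein = {
        receptor_label: [(r["time_min"], r["receptor_fit"]) for r in records],
        arrestin_label: [(r["time_min"], r["arrestin_fit"]) for r in records],
    }
    points, trends = pr.concentration_series(
        fits_by_protein, epsilon, area_factor,
        receptor_label=receptor_label, arrestin_label=arrestin_label,
    )
    return {
        "records": records,
        "fixed_C": fixed_C,
        "points": points,
        "trends": trends,
        "arrestin_total": [
            (r["time_min"], pr.arrestin_total_signal(r["arrestin_fit"])) for r in records
        ],
        "units": "concentration in (a.u.*px)/(a.u./molecule * um^2), relative",
        "profile_coordinate": "x starts at 1 at the intracellular ROI edge",
    }
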
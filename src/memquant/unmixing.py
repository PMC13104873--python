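"""Pixel-level linear spectral unmixing of two-fluorophore images.

Each pixel of a spectrally resolved stack carries a composite emission
spectrum modeled as an abundance-weighted sum of elementary fluorophore
spectra.  Abundances are the least-squares solution per pixel; by default a
nonnegativity constraint is enforced by active-set clamping (for two spectra
the constrained optimum is one of three closed-form candidates), which
prevents negative "concentrations" in dim pixels.  The math is written for k
spectra but the supported, tested case is k = 2 (mEGFP-like + mCitrine-like).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import IntensityMap, SpectralStack


@dataclass
class ElementarySpectrum:
    """Normalized per-channel emission signature of a single fluorophore."""

    weights: np.ndarray
    fluorophore_label: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1D")
        if np.any(self.weights < 0):
            raise ValueError("spectral weights must be nonnegative")
        total = float(self.weights.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("spectral weights must sum to 1 (within 1e-9)")


@dataclass
class UnmixResult:
    """Per-fluorophore abundance maps plus the per-pixel residual norm."""

    abundance: dict  # label -> IntensityMap
    residual: np.ndarray
    nonnegative: bool  # which solver branch produced the abundances


def derive_elementary_spectrum(
    stack: SpectralStack, mask: np.ndarray, label: str = "",
    background: np.ndarray | None = None,
) -> ElementarySpectrum:
    """Elementary spectrum from a single-fluorophore stack: channel-wise sum
    over masked pixels after background subtraction, normalized to unit sum.

    ``background`` is a per-channel offset (e.g. from a cell-free corner
    region); negative post-background channels are clipped to zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape[:2]:
        raise ValueError("mask shape must match the stack's spatial shape")
    if mask.sum() == 0:
        raise ValueError("empty mask")
    summed = stack.intensities[mask].sum(axis=0)
    if background is not None:
        summed = summed - np.asarray(background, dtype=float) * mask.sum()
    if np.any(summed < 0):
        summed = np.clip(summed, 0.0, None)
    total = summed.sum()
    if total <= 0:
        raise ValueError("no signal above background in the masked region")
    return ElementarySpectrum(summed / total, fluorophore_label=label)


def _solve_two(
    Y: np.ndarray, S: np.ndarray, nonnegative: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares abundances for k=2 over a batch of spectra.

    ``Y`` is (n_pixels, n_channels), ``S`` is (n_channels, 2).  The
    nonnegative branch clamps via the active set: for two components the
    constrained optimum is the unconstrained solution if feasible, else the
    better of the two single-component nonnegative fits.
    """
    G = S.T @ S  # 2x2 Gram matrix
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    if det <= 1e-12 * G[0, 0] * G[1, 1]:
        raise np.linalg.LinAlgError("elementary spectra are not linearly independent")
    b = Y @ S  # (n, 2)
    inv = np.array([[G[1, 1], -G[0, 1]], [-G[0, 1], G[0, 0]]]) / det
    a = b @ inv.T  # unconstrained solution
    if nonnegative:
        neg = (a < 0).any(axis=1)
        if np.any(neg):
            a0 = np.clip(b[neg, 0] / G[0, 0], 0.0, None)
            a1 = np.clip(b[neg, 1] / G[1, 1], 0.0, None)
            # residual^2 = |Y|^2 - 2 a.b + a.G.a ; compare the two 1D branches
            r0 = -2.0 * a0 * b[neg, 0] + a0**2 * G[0, 0]
            r1 = -2.0 * a1 * b[neg, 1] + a1**2 * G[1, 1]
            pick1 = r1 < r0
            sub = np.zeros((int(neg.sum()), 2))
            sub[~pick1, 0] = a0[~pick1]
            sub[pick1, 1] = a1[pick1]
            a[neg] = sub
    model = a @ S.T
    residual = np.linalg.norm(Y - model, axis=1)
    return a, residual


def unmix_pixel(composite, spectra, nonnegative: bool = True):
    """Unmix one composite spectrum.  Returns ``(abundances, residual)``."""
    Y = np.asarray(composite, dtype=float)[None, :]
    S = np.column_stack([s.weights for s in spectra])
    if S.shape[0] != Y.shape[1]:
        raise ValueError("channel count mismatch between composite and spectra")
    a, r = _solve_two(Y, S, nonnegative)
    return a[0], float(r[0])


def unmix_stack(
    stack: SpectralStack, spectra, nonnegative: bool = True,
    background: np.ndarray | None = None,
) -> UnmixResult:
    """Pixel-wise unmixing of a whole stack into per-fluorophore abundance
    maps congruent with the input, plus a residual map."""
    S = np.column_stack([s.weights for s in spectra])
    if S.shape[0] != stack.n_channels:
        raise ValueError("channel count mismatch between stack and spectra")
    h, w, _ = stack.shape
    Y = stack.intensities.reshape(h * w, -1)
    if background is not None:
        Y = Y - np.asarray(background, dtype=float)[None, :]
    a, r = _solve_two(Y, S, nonnegative)
    maps = {}
    for j, s in enumerate(spectra):
        maps[s.fluorophore_label or f"component_{j}"] = IntensityMap(
            a[:, j].reshape(h, w),
            fluorophore_label=s.fluorophore_label,
            plane_label=stack.plane_label,
            timestamp=stack.timestamp,
        )
    return UnmixResult(abundance=maps, residual=r.reshape(h, w), nonnegative=nonnegative)


def estimate_background(stack: SpectralStack, corner: tuple[int, int] = (12, 12)) -> np.ndarray:
    """Per-channel constant background from a cell-free corner region
    (default: the top-left ``corner`` window), as the per-channel mean."""
    h, w = corner
    return stack.intensities[:h, :w].reshape(-1, stack.n_channels).mean(axis=0)
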
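"""Core domain containers for the imaging pipeline.

All axial positions are stored internally in nanometers; positive z points
from the coverslip into the sample.  Images are (row, col[, channel]) arrays
with 0-based indices.  Micrometers appear only at presentation boundaries
(CLI output, plot labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FormatError(ValueError):
    """An input file or array violates the expected layout."""


class BeadLostError(RuntimeError):
    """The live bead image no longer matches any reference template."""


@dataclass
class SpectralStack:
    """A spectrally resolved image: rows x cols x wavelength channels (a.u.).

    ``channel_wavelengths`` are channel-center wavelengths in nm, strictly
    increasing (nominally spanning 450-600 nm over 16 channels).
    """

    intensities: np.ndarray
    channel_wavelengths: np.ndarray
    pixel_size: float = 250.0  # nm per pixel
    timestamp: float = 0.0  # s
    plane_label: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.channel_wavelengths = np.asarray(self.channel_wavelengths, dtype=float)
        if self.intensities.ndim != 3:
            raise FormatError("intensities must be rows x cols x channels")
        if self.intensities.shape[2] < 2:
            raise FormatError("a spectral stack needs at least 2 channels")
        if self.channel_wavelengths.shape != (self.intensities.shape[2],):
            raise FormatError("one wavelength per channel required")
        if np.any(np.diff(self.channel_wavelengths) <= 0):
            raise FormatError("channel wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]


@dataclass
class IntensityMap:
    """A single-fluorophore 2D intensity image (a.u.)."""

    values: np.ndarray
    fluorophore_label: str = ""
    plane_label: str = ""
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2D array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ScanSchedule:
    """The multi-plane scan protocol: plane offsets are axial offsets from a
    baseline plane (nm); ``inter_scan_delay`` is the programmed pause between
    successive z-scans (s)."""

    plane_offsets: list = field(default_factory=lambda: [0.0, 590.0, 2340.0])
    n_scans: int = 5
    inter_scan_delay: float = 50.0

    def __post_init__(self) -> None:
        self.plane_offsets = [float(p) for p in self.plane_offsets]
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if not all(np.isfinite(self.plane_offsets)):
            raise ValueError("plane offsets must be finite")


@dataclass
class BeadZStack:
    """Reflected-light frames of fiducial beads, one per reported objective
    position.  Positions are the *reported* stage readouts (nm); the true
    focal displacement differs by the axial calibration factor."""

    frames: np.ndarray
    reported_positions: np.ndarray
    pixel_size: float = 250.0  # nm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.reported_positions = np.asarray(self.reported_positions, dtype=float)
        if self.frames.ndim != 3:
            raise FormatError("frames must be n_frames x rows x cols")
        if self.frames.shape[0] < 3:
            raise ValueError("need at least 3 frames")
        if self.reported_positions.shape != (self.frames.shape[0],):
            raise ValueError("one reported position per frame required")
        d = np.diff(self.reported_positions)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("reported positions must be strictly monotone")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]
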
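"""Readers and writers for the pipeline's on-disk formats.

Image stacks travel as multi-page TIFF with the channel (or frame) axis in
page order; acquisition metadata that TIFF does not carry (wavelengths, pixel
size, axial positions, timestamps) lives in a JSON sidecar named
``<stem>.meta.json`` next to the image.  Traces, profiles and concentration
series are CSV; spectra, fit results and calibration records are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationResult
from .types import BeadZStack, FormatError, SpectralStack

TRACE_COLUMNS = ["t_s", "target_nm", "measured_nm", "stage_nm", "delta_gp_nm", "phase"]


def _sidecar(path: Path) -> Path:
    return path.parent / (path.name + ".meta.json")


def write_spectral_stack(stack: SpectralStack, path) -> None:
    """Write a spectral stack as multi-page TIFF (one page per channel) plus
    a JSON metadata sidecar."""
    path = Path(path)
    pages = np.moveaxis(stack.intensities, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "channel_wavelengths_nm": stack.channel_wavelengths.tolist(),
        "pixel_size_nm": stack.pixel_size,
        "timestamp_s": stack.timestamp,
        "plane_label": stack.plane_label,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_spectral_stack(path) -> SpectralStack:
    """Read a multi-page TIFF as a spectral stack (pages are channels),
    populating metadata from the sidecar when present."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pages = tifffile.imread(path)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise OSError(f"unreadable image file {path}: {exc}") from exc
    if pages.ndim == 2:
        raise FormatError("single-page file: a spectral stack needs >= 2 channels")
    if pages.ndim != 3:
        raise FormatError(f"expected a multi-page 2D raster, got shape {pages.shape}")
    intensities = np.moveaxis(pages.astype(float), 0, 2)
    side = _sidecar(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    wavelengths = meta.get(
        "channel_wavelengths_nm",
        np.linspace(450.0, 600.0, intensities.shape[2]).tolist(),
    )
    return SpectralStack(
        intensities,
        np.asarray(wavelengths, dtype=float),
        pixel_size=meta.get("pixel_size_nm", 250.0),
        timestamp=meta.get("timestamp_s", 0.0),
        plane_label=meta.get("plane_label", ""),
    )


def write_bead_zstack(stack: BeadZStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "reported_positions_nm": stack.reported_positions.tolist(),
        "pixel_size_nm": stack.pixel_size,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_bead_zstack(path) -> BeadZStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return BeadZStack(
        frames,
        np.asarray(meta["reported_positions_nm"], dtype=float),
        pixel_size=meta.get("pixel_size_nm", 250.0),
    )


def write_trace(trace: pd.DataFrame, path) -> None:
    """Write a tracking/stage trace as CSV (header + one row per sample),
    numeric columns at 0.1 nm precision or better."""
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace lacks required columns: {missing}")
    cols = TRACE_COLUMNS + [c for c in trace.columns if c not in TRACE_COLUMNS]
    trace[cols].to_csv(path, index=False, float_format="%.4f")


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_spectra(spectra: dict, path) -> None:
    """Spectra JSON: {label: [per-channel weights]}."""
    payload = {k: np.asarray(v, dtype=float).tolist() for k, v in spectra.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_spectra(path) -> dict:
    return {k: np.asarray(v, dtype=float) for k, v in json.loads(Path(path).read_text()).items()}


def write_calibration(result: CalibrationResult, path) -> None:
    Path(path).write_text(json.dumps({
        "factor": result.factor,
        "method": result.method,
        "surface_plane_nm_reported": result.surface_plane,
        "center_planes_nm_reported": result.center_planes,
        "bead_radii_nm": result.bead_radii_used,
    }, indent=1))


def read_calibration(path) -> CalibrationResult:
    d = json.loads(Path(path).read_text())
    return CalibrationResult(
        factor=d["factor"],
        method=d["method"],
        surface_plane=d.get("surface_plane_nm_reported"),
        center_planes=d.get("center_planes_nm_reported", []),
        bead_radii_used=d.get("bead_radii_nm", []),
    )
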
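"""Normalization and qualitative colocalization mapping of basolateral-
membrane images.

These maps are presentation-layer products: each channel is normalized to a
representative high-signal punctum (so frames and channels are visually
comparable) and the pixel-wise product of the two normalized channels
highlights co-localized receptor/arrestin puncta.  Nothing here feeds the
quantitative concentration pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import IntensityMap


@dataclass
class NormalizedMap:
    """An intensity map divided by a reference punctum intensity."""

    values: np.ndarray
    reference_punctum: tuple[int, int]
    reference_intensity: float
    fluorophore_label: str = ""

    @property
    def shape(self):
        return self.values.shape


def normalize_map(
    amap: IntensityMap, punctum: tuple[int, int], neighborhood: int = 3
) -> NormalizedMap:
    """Divide all pixels by the punctum intensity.

    The reference intensity is the mean over a ``neighborhood`` x
    ``neighborhood`` window centered on the punctum (noise robustness); the
    window is clipped at image borders.
    """
    r, c = punctum
    h, w = amap.shape
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError("punctum outside the map")
    k = neighborhood // 2
    ref = float(amap.values[max(0, r - k):r + k + 1, max(0, c - k):c + k + 1].mean())
    if ref <= 0:
        raise ValueError("reference punctum intensity must be positive")
    return NormalizedMap(
        amap.values / ref,
        reference_punctum=(r, c),
        reference_intensity=ref,
        fluorophore_label=amap.fluorophore_label,
    )


def colocalization_map(map_a: NormalizedMap, map_b: NormalizedMap) -> IntensityMap:
    """Pixel-wise product of two normalized maps (symmetric in its arguments);
    maxima mark concurrent localization of the two proteins."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must be congruent")
    return IntensityMap(map_a.values * map_b.values, fluorophore_label="colocalization")


def rank_puncta(map_a: IntensityMap, map_b: IntensityMap, k: int = 5, min_separation: int = 3):
    """Optional helper: candidate reference puncta ranked by joint brightness
    (product of the two channels), greedily enforcing a minimum separation.
    Punctum choice remains an explicit input to :func:`normalize_map`."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must be congruent")
    joint = map_a.values * map_b.values
    order = np.argsort(joint, axis=None)[::-1]
    picks = []
    for flat in order:
        r, c = np.unravel_index(flat, joint.shape)
        if all(max(abs(r - pr), abs(c - pc)) >= min_separation for pr, pc in picks):
            picks.append((int(r), int(c)))
        if len(picks) == k:
            break
    return picks
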
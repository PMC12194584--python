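"""Phantom-body segmentation and centroid estimation.

The rotating-ROI search is anchored 55 mm from the centroid of the phantom
body, so the first stage of every measurement is to separate the
water-equivalent body (≈ 0–90 HU) from surrounding air (≈ −1000 HU) and
compute its center of mass in mm.

The centroid is *binary* (unweighted mean of foreground pixel centers): an
intensity-weighted centroid would be biased by the low-contrast insert,
whereas the binary centroid is insensitive to internal structure.  The
threshold default of −300 HU sits midway between air and body and tolerates
noise SDs far beyond anything a clinical reconstruction produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import PhantomNotFoundError
from .image import HUImage

DEFAULT_THRESHOLD_HU = -300.0

#: plausible equivalent-diameter range (mm) for the ACR phantom body (~200 mm)
BODY_DIAMETER_RANGE_MM = (150.0, 250.0)


@dataclass(frozen=True)
class PhantomMask:
    """Binary footprint of the phantom body, congruent with its image."""

    mask: np.ndarray

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class CentroidEstimate:
    """Center of the phantom body in mm, plus the equivalent circular diameter.

    ``plausible_body`` is False when the equivalent diameter falls outside the
    nominal ACR range [150, 250] mm — a hint that the slice may not show the
    expected module; measurement still proceeds.
    """

    center_mm: tuple[float, float]
    equivalent_diameter_mm: float

    @property
    def plausible_body(self) -> bool:
        lo, hi = BODY_DIAMETER_RANGE_MM
        return lo <= self.equivalent_diameter_mm <= hi


def segment_phantom(image: HUImage, threshold_hu: float = DEFAULT_THRESHOLD_HU) -> PhantomMask:
    """Largest connected component of ``values > threshold``, holes filled.

    Hole filling makes the mask robust to hypodense internal structure;
    keeping only the largest component discards table/couch fragments.

    Raises
    ------
    PhantomNotFoundError
        If no pixel exceeds the threshold.
    """
    fg = image.values > threshold_hu
    if not fg.any():
        raise PhantomNotFoundError(
            f"no phantom found: no pixel above {threshold_hu} HU"
        )
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (int(np.argmax(sizes)) + 1)
    fg = ndimage.binary_fill_holes(fg)
    return PhantomMask(fg)


def phantom_centroid(mask: PhantomMask, image: HUImage) -> CentroidEstimate:
    """Unweighted centroid of the mask in mm, with equivalent diameter.

    center = mean of foreground pixel centers; equivalent diameter
    = 2·sqrt(area_mm² / π) where area_mm² = pixel_count × pixel area.
    """
    if mask.pixel_count == 0:
        raise PhantomNotFoundError("empty phantom mask")
    rows, cols = np.nonzero(mask.mask)
    rs, cs = image.spacing_mm
    center = (float(cols.mean() * cs), float(rows.mean() * rs))
    area_mm2 = mask.pixel_count * rs * cs
    eq_diameter = 2.0 * float(np.sqrt(area_mm2 / np.pi))
    return CentroidEstimate(center_mm=center, equivalent_diameter_mm=eq_diameter)
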
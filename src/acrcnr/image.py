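"""Calibrated CT images in Hounsfield units with physical pixel geometry.

The universal input of the package is :class:`HUImage`: a 2-D array of CT
numbers plus the (row, column) pixel spacing in mm.  All downstream geometry
(the 55 mm radial search, ROI diameters) is computed in millimetres, so a
change of reconstruction FOV only changes the spacing and nothing else.

Coordinate convention
---------------------
Positions are ``(x, y)`` in mm with the origin at the *center* of the
top-left pixel; ``x`` increases with columns (rightward on a displayed
slice), ``y`` increases with rows (downward).  Angles are measured from
12 o'clock of the displayed image, clockwise positive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset

from .errors import CalibrationError, ValidationError

MIN_MATRIX = 64


@dataclass(frozen=True)
class HUImage:
    """A single CT slice calibrated to Hounsfield units.

    Parameters
    ----------
    values : ndarray
        2-D float array of CT numbers (air ≈ −1000, water ≈ 0).
    spacing_mm : tuple of float
        ``(row_spacing, col_spacing)`` in mm per pixel.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValidationError(f"expected a 2-D array, got ndim={v.ndim}")
        if v.shape[0] < MIN_MATRIX or v.shape[1] < MIN_MATRIX:
            raise ValidationError(
                f"matrix {v.shape} smaller than minimum {MIN_MATRIX}×{MIN_MATRIX}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("image contains non-finite CT numbers")
        rs, cs = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        if rs <= 0 or cs <= 0:
            raise ValidationError(f"pixel spacing must be positive, got {self.spacing_mm}")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "spacing_mm", (rs, cs))

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def width_mm(self) -> float:
        """Physical width: cols × col_spacing."""
        return self.cols * self.spacing_mm[1]

    @property
    def height_mm(self) -> float:
        return self.rows * self.spacing_mm[0]

    @property
    def center_mm(self) -> tuple[float, float]:
        """(x, y) of the geometric image center in mm."""
        return ((self.cols - 1) / 2 * self.spacing_mm[1],
                (self.rows - 1) / 2 * self.spacing_mm[0])

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of pixel-center x (per column) and y (per row) in mm."""
        xs = np.arange(self.cols) * self.spacing_mm[1]
        ys = np.arange(self.rows) * self.spacing_mm[0]
        return xs, ys

    def contains_circle(self, center_mm: tuple[float, float], radius_mm: float) -> bool:
        """Whether a circle lies fully inside the physical image extent."""
        cx, cy = center_mm
        rs, cs = self.spacing_mm
        return (
            cx - radius_mm >= -cs / 2
            and cx + radius_mm <= (self.cols - 1) * cs + cs / 2
            and cy - radius_mm >= -rs / 2
            and cy + radius_mm <= (self.rows - 1) * rs + rs / 2
        )


def image_from_array(values, spacing_mm) -> HUImage:
    """Wrap a raw HU array into an :class:`HUImage`, validating its contract.

    Raises :class:`ValidationError` for ragged input or non-positive spacing.
    """
    try:
        arr = np.asarray(values, dtype=np.float64)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"grid is not rectangular: {exc}") from exc
    return HUImage(arr, tuple(spacing_mm))


def _require(ds: Dataset, attr: str) -> None:
    if not hasattr(ds, attr) or getattr(ds, attr) is None:
        raise CalibrationError(f"DICOM object is missing required attribute {attr!r}")


def load_dicom_slice(path) -> HUImage:
    """Read one single-frame CT DICOM file into a calibrated :class:`HUImage`.

    HU = stored_value × RescaleSlope + RescaleIntercept (slope/intercept
    default to 1/0 when absent); spacing is taken from PixelSpacing in mm.
    """
    ds = pydicom.dcmread(str(path))
    _require(ds, "PixelData")
    _require(ds, "PixelSpacing")
    photometric = getattr(ds, "PhotometricInterpretation", "MONOCHROME2")
    if not str(photometric).startswith("MONOCHROME"):
        raise CalibrationError(
            f"unsupported PhotometricInterpretation {photometric!r}; expected MONOCHROME"
        )
    stored = ds.pixel_array
    if stored.ndim != 2:
        raise CalibrationError("expected a single-frame image")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = stored.astype(np.float64) * slope + intercept
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    meta = {
        "path": str(path),
        "instance_number": int(getattr(ds, "InstanceNumber", 0) or 0),
    }
    return HUImage(hu, spacing, meta=meta)


def load_dicom_stack(directory) -> list[HUImage]:
    """Read every DICOM file in a directory, ordered by InstanceNumber."""
    paths = sorted(
        os.path.join(directory, name)
        for name in os.listdir(directory)
        if not name.startswith(".")
    )
    slices = []
    for p in paths:
        if not os.path.isfile(p):
            continue
        try:
            slices.append(load_dicom_slice(p))
        except pydicom.errors.InvalidDicomError:
            continue
    slices.sort(key=lambda im: im.meta.get("instance_number", 0))
    return slices


def write_hu_text(image: HUImage, path) -> None:
    """Dump an image as a plain tab-delimited text grid (for inspection).

    The first header line records the pixel spacing so the dump round-trips.
    """
    header = f"row_spacing_mm={image.spacing_mm[0]!r} col_spacing_mm={image.spacing_mm[1]!r}"
    np.savetxt(path, image.values, fmt="%.3f", delimiter="\t", header=header)
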
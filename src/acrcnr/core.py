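"""The statistical rotating-ROI CNR measurement.

The method: a circular ROI (default 25 mm diameter) is placed 55 mm from the
phantom centroid and stepped clockwise around a full rotation in 2°
increments.  The mean CT number at each position forms an angular profile;
the largest low-contrast object of the ACR phantom's low-contrast module sits
at that radius, so the profile's maximum marks its angular position.  CNR is
then

    CNR = (mean_object − mean_background) / SD_background

with the object ROI at the detected position and the background ROI at the
phantom centroid.  Because the search radius is tied to the *measured*
centroid, the method tolerates phantom misalignment.

Angle convention: 0° at 12 o'clock of the displayed image, clockwise
positive; an ROI center at angle θ is ``centroid + radius·(sin θ, −cos θ)``
in (x, y) display coordinates with y pointing down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateStatisticsError,
    GeometryError,
    StatisticsError,
    ValidationError,
)
from .geometry import CentroidEstimate, phantom_centroid, segment_phantom
from .image import HUImage


@dataclass(frozen=True)
class SearchConfig:
    """Geometry of the rotating-ROI search.

    radius_mm
        Radial distance of the rotating-ROI centers from the phantom
        centroid; 55 mm is the known radial position of the 25 mm
        low-contrast object in the ACR phantom's module 2.
    roi_diameter_mm
        Diameter of the rotating (object) ROI.  25 mm matches the object:
        a matched ROI maximizes the mean-CT-number response.
    step_deg
        Clockwise angular step; must divide 360.
    background_roi_diameter_mm
        Diameter of the background ROI placed at the phantom centroid.
    start_angle_deg
        Angle of the first ROI; the search is rotation-complete so the
        starting angle is arbitrary.
    """

    radius_mm: float = 55.0
    roi_diameter_mm: float = 25.0
    step_deg: float = 2.0
    background_roi_diameter_mm: float = 25.0
    start_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("radius_mm", "roi_diameter_mm", "step_deg", "background_roi_diameter_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if abs(360.0 / self.step_deg - round(360.0 / self.step_deg)) > 1e-9:
            raise ValidationError(f"step_deg={self.step_deg} must divide 360")

    @property
    def n_steps(self) -> int:
        return int(round(360.0 / self.step_deg))


@dataclass(frozen=True)
class ROIStats:
    """Mean and sample SD (n−1 denominator) of CT numbers inside one ROI."""

    mean_hu: float
    sd_hu: float
    n_pixels: int


@dataclass(frozen=True)
class AngularProfile:
    """Mean CT number versus ROI angle over one full rotation."""

    angles_deg: np.ndarray
    mean_hu: np.ndarray

    @property
    def argmax_index(self) -> int:
        """Index of the maximum; first occurrence on ties."""
        return int(np.argmax(self.mean_hu))

    @property
    def argmax_deg(self) -> float:
        return float(self.angles_deg[self.argmax_index])


@dataclass(frozen=True)
class ObjectLocation:
    """Detected center of the largest low-contrast object."""

    center_mm: tuple[float, float]
    angle_deg: float


@dataclass(frozen=True)
class CNRResult:
    """Contrast, noise and CNR with the ROI statistics that produced them.

    contrast_hu is the *signed* difference object − background; noise_hu is
    the background sample SD; cnr = contrast_hu / noise_hu, so
    cnr × noise_hu == contrast_hu holds exactly.
    """

    contrast_hu: float
    noise_hu: float
    cnr: float
    object_stats: ROIStats
    background_stats: ROIStats


def roi_center_at_angle(
    phantom_center: tuple[float, float], radius_mm: float, angle_deg: float
) -> tuple[float, float]:
    """ROI center for an angle measured clockwise from 12 o'clock."""
    theta = math.radians(angle_deg)
    return (
        phantom_center[0] + radius_mm * math.sin(theta),
        phantom_center[1] - radius_mm * math.cos(theta),
    )


def _roi_values(image: HUImage, center_mm, diameter_mm: float) -> np.ndarray:
    """1-D array of CT numbers whose pixel centers fall inside the circle.

    Works on the circle's bounding box only, so per-ROI cost is independent
    of the matrix size — this is what makes the 180-position search cheap.
    """
    r = diameter_mm / 2.0
    if not image.contains_circle(center_mm, r):
        raise GeometryError(
            f"ROI of diameter {diameter_mm} mm at {center_mm} exceeds image bounds"
        )
    rs, cs = image.spacing_mm
    cx, cy = center_mm
    c0 = max(int(math.floor((cx - r) / cs)), 0)
    c1 = min(int(math.ceil((cx + r) / cs)) + 1, image.cols)
    r0 = max(int(math.floor((cy - r) / rs)), 0)
    r1 = min(int(math.ceil((cy + r) / rs)) + 1, image.rows)
    xs = np.arange(c0, c1) * cs - cx
    ys = np.arange(r0, r1) * rs - cy
    inside = (ys[:, None] ** 2 + xs[None, :] ** 2) <= r * r
    return image.values[r0:r1, c0:c1][inside]


def circular_roi_mask(image: HUImage, center_mm, diameter_mm: float) -> np.ndarray:
    """Boolean mask selecting pixels whose centers lie within the circle.

    Selection is purely geometric (Euclidean distance in mm); image values
    are irrelevant.  Raises :class:`GeometryError` if the circle does not fit
    inside the image.
    """
    r = diameter_mm / 2.0
    if not image.contains_circle(center_mm, r):
        raise GeometryError(
            f"circle of diameter {diameter_mm} mm at {center_mm} exceeds image bounds"
        )
    xs, ys = image.pixel_centers()
    dx = xs - center_mm[0]
    dy = ys - center_mm[1]
    return (dy[:, None] ** 2 + dx[None, :] ** 2) <= r * r


def roi_stats(image: HUImage, mask: np.ndarray) -> ROIStats:
    """Mean and sample SD of the CT numbers selected by a boolean mask."""
    vals = image.values[np.asarray(mask, dtype=bool)]
    return _stats_from_values(vals)


def _stats_from_values(vals: np.ndarray) -> ROIStats:
    n = int(vals.size)
    if n < 2:
        raise StatisticsError(f"ROI selects {n} pixel(s); at least 2 required")
    return ROIStats(
        mean_hu=float(vals.mean()),
        sd_hu=float(vals.std(ddof=1)),
        n_pixels=n,
    )


def angular_profile(
    image: HUImage, phantom_center, cfg: SearchConfig | None = None
) -> AngularProfile:
    """Mean CT number of the rotating ROI at each step of one full rotation."""
    cfg = cfg or SearchConfig()
    n = cfg.n_steps
    angles = (cfg.start_angle_deg + cfg.step_deg * np.arange(n)) % 360.0
    means = np.empty(n)
    for k in range(n):
        center = roi_center_at_angle(phantom_center, cfg.radius_mm, float(angles[k]))
        try:
            vals = _roi_values(image, center, cfg.roi_diameter_mm)
        except GeometryError as exc:
            raise GeometryError(f"at angle {angles[k]:.1f}°: {exc}") from exc
        means[k] = vals.mean()
    return AngularProfile(angles_deg=angles, mean_hu=means)


def locate_low_contrast_object(
    profile: AngularProfile, phantom_center, cfg: SearchConfig | None = None
) -> ObjectLocation:
    """Position of the profile maximum (first occurrence on ties)."""
    cfg = cfg or SearchConfig()
    angle = profile.argmax_deg
    return ObjectLocation(
        center_mm=roi_center_at_angle(phantom_center, cfg.radius_mm, angle),
        angle_deg=angle,
    )


def measure_cnr(
    image: HUImage,
    object_center,
    background_center,
    cfg: SearchConfig | None = None,
) -> CNRResult:
    """CNR from an object ROI and a background ROI.

    contrast = object mean − background mean (signed); noise = background
    sample SD.  A zero background SD means a noiseless image, for which CNR
    is undefined.
    """
    cfg = cfg or SearchConfig()
    obj = _stats_from_values(_roi_values(image, object_center, cfg.roi_diameter_mm))
    bg = _stats_from_values(
        _roi_values(image, background_center, cfg.background_roi_diameter_mm)
    )
    if bg.sd_hu == 0.0:
        raise DegenerateStatisticsError("noiseless image; CNR undefined")
    contrast = obj.mean_hu - bg.mean_hu
    return CNRResult(
        contrast_hu=contrast,
        noise_hu=bg.sd_hu,
        cnr=contrast / bg.sd_hu,
        object_stats=obj,
        background_stats=bg,
    )


@dataclass(frozen=True)
class AutoCNROutcome:
    """Everything the end-to-end measurement produced, for reporting/QC."""

    result: CNRResult
    location: ObjectLocation
    centroid: CentroidEstimate
    profile: AngularProfile
    warnings: tuple[str, ...] = field(default=())


def locate_object(
    image: HUImage, cfg: SearchConfig | None = None
) -> tuple[ObjectLocation, CentroidEstimate, AngularProfile, tuple[str, ...]]:
    """Localization stages only: segment phantom → centroid → rotating-ROI
    angular profile → object at the profile maximum.

    Usable on noiseless images, where a full CNR is undefined.
    """
    cfg = cfg or SearchConfig()
    warnings: list[str] = []
    mask = segment_phantom(image)
    centroid = phantom_centroid(mask, image)
    if not centroid.plausible_body:
        warnings.append(
            "segmentation: equivalent diameter "
            f"{centroid.equivalent_diameter_mm:.1f} mm outside nominal "
            "[150, 250] mm; possibly the wrong module or object"
        )
    try:
        profile = angular_profile(image, centroid.center_mm, cfg)
    except GeometryError as exc:
        raise GeometryError(f"angular search: {exc}") from exc
    location = locate_low_contrast_object(profile, centroid.center_mm, cfg)
    return location, centroid, profile, tuple(warnings)


def auto_cnr(image: HUImage, cfg: SearchConfig | None = None) -> AutoCNROutcome:
    """End-to-end automatic measurement on one slice.

    Pipeline: :func:`locate_object` followed by the CNR computation with
    the background ROI at the phantom centroid.  Stage failures propagate
    with the stage named in the message.
    """
    cfg = cfg or SearchConfig()
    location, centroid, profile, warnings = locate_object(image, cfg)
    try:
        result = measure_cnr(image, location.center_mm, centroid.center_mm, cfg)
    except DegenerateStatisticsError as exc:
        raise DegenerateStatisticsError(f"cnr measurement: {exc}") from exc
    return AutoCNROutcome(
        result=result,
        location=location,
        centroid=centroid,
        profile=profile,
        warnings=warnings,
    )
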
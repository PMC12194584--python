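"""Synthetic ACR low-contrast-module slices with known ground truth.

A simulated slice is a ~200 mm water-equivalent disc (background ≈ 90 HU)
in air (−1000 HU), carrying one 25 mm low-contrast disc at 55 mm radial
distance from the phantom center at a configurable angle, with additive
white Gaussian noise on the body.  Disc edges are antialiased by area
fraction (4× supersampling) so ROI means are not biased by rasterization.

This emulates what matters to a mean/SD-based measurement — contrast,
noise magnitude, geometry, misalignment — and deliberately not the rest of
CT physics: noise is white rather than ramp-filtered/streaked, there is no
beam hardening and no kernel MTF.  Reconstruction-kernel and exposure
effects are emulated purely by the noise SD (the 2.7–50 HU range seen
across clinical protocols).

Determinism: ``generate_slice`` is a pure function of (config, slice_seed);
``generate_stack`` derives per-slice seeds from (config.seed, slice index)
via :func:`derive_slice_seed`, so stacks are reproducible and slices are
independent.
"""

from __future__ import annotations

import datetime
import os
from dataclasses import dataclass, replace

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .errors import ConfigError
from .image import HUImage

_SUPERSAMPLE = 4

#: diameters (mm) of the smaller low-contrast cylinder series, drawn only
#: for visual realism; no measurement or oracle ever uses them.
SMALL_CYLINDER_DIAMETERS_MM = (6.0, 5.0, 4.0, 3.0, 2.0)


@dataclass(frozen=True)
class SyntheticPhantomConfig:
    """Full parameterization of a simulated low-contrast-module slice.

    Defaults encode the canonical study conditions: 235 mm FOV on a 512
    matrix (0.459 mm pixels), 200 mm body at 90 HU, a 25 mm object at
    55 mm radius with +6 HU contrast, noise SD 3 HU, 20-slice stacks.
    """

    fov_mm: float = 235.0
    matrix: int = 512
    body_diameter_mm: float = 200.0
    background_hu: float = 90.0
    air_hu: float = -1000.0
    contrast_hu: float = 6.0
    object_angle_deg: float = 134.0
    object_radius_mm: float = 55.0
    object_diameter_mm: float = 25.0
    noise_sd_hu: float = 3.0
    offset_mm: tuple[float, float] = (0.0, 0.0)
    n_slices: int = 20
    seed: int = 0
    draw_small_cylinders: bool = False

    def __post_init__(self) -> None:
        if self.object_radius_mm + self.object_diameter_mm / 2 >= self.body_diameter_mm / 2:
            raise ConfigError("object does not fit inside the phantom body")
        max_off = max(abs(self.offset_mm[0]), abs(self.offset_mm[1]))
        if self.fov_mm < self.body_diameter_mm + 2 * max_off:
            raise ConfigError("FOV too small for the body diameter plus offset")
        if self.noise_sd_hu < 0:
            raise ConfigError("noise SD must be non-negative")
        if self.matrix < 64:
            raise ConfigError("matrix must be at least 64")
        if self.n_slices < 1:
            raise ConfigError("n_slices must be at least 1")

    @property
    def spacing_mm(self) -> float:
        return self.fov_mm / self.matrix


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, for recovery tests."""

    object_center_mm: tuple[float, float]
    object_angle_deg: float
    phantom_center_mm: tuple[float, float]
    true_contrast_hu: float
    true_noise_sd_hu: float


def derive_slice_seed(seed: int, k: int) -> int:
    """Deterministic per-slice seed for slice ``k`` of a stack."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0])


def _disc_coverage(
    n: int, spacing: float, center: tuple[float, float], radius: float
) -> np.ndarray:
    """Per-pixel area fraction covered by a disc, via 4×4 supersampling.

    Computed on the disc's bounding box only and pasted into a full-size
    zero array.
    """
    cx, cy = center
    pad = 1
    c0 = max(int(np.floor((cx - radius) / spacing)) - pad, 0)
    c1 = min(int(np.ceil((cx + radius) / spacing)) + pad + 1, n)
    r0 = max(int(np.floor((cy - radius) / spacing)) - pad, 0)
    r1 = min(int(np.ceil((cy + radius) / spacing)) + pad + 1, n)
    sub = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5  # pixel units
    acc = np.zeros((r1 - r0, c1 - c0))
    xs = np.arange(c0, c1) * spacing
    ys = np.arange(r0, r1) * spacing
    for dy in sub:
        for dx in sub:
            ddx = xs + dx * spacing - cx
            ddy = ys + dy * spacing - cy
            acc += (ddy[:, None] ** 2 + ddx[None, :] ** 2) <= radius * radius
    full = np.zeros((n, n))
    full[r0:r1, c0:c1] = acc / (_SUPERSAMPLE * _SUPERSAMPLE)
    return full


def _object_center(cfg: SyntheticPhantomConfig, phantom_center) -> tuple[float, float]:
    theta = np.radians(cfg.object_angle_deg)
    return (
        phantom_center[0] + cfg.object_radius_mm * float(np.sin(theta)),
        phantom_center[1] - cfg.object_radius_mm * float(np.cos(theta)),
    )


def generate_slice(
    cfg: SyntheticPhantomConfig, slice_seed: int = 0
) -> tuple[HUImage, GroundTruth]:
    """Render one slice; deterministic given (cfg, slice_seed)."""
    n, sp = cfg.matrix, cfg.spacing_mm
    image_center = ((n - 1) / 2 * sp, (n - 1) / 2 * sp)
    phantom_center = (
        image_center[0] + cfg.offset_mm[0],
        image_center[1] + cfg.offset_mm[1],
    )
    body = _disc_coverage(n, sp, phantom_center, cfg.body_diameter_mm / 2)
    obj_center = _object_center(cfg, phantom_center)
    obj = _disc_coverage(n, sp, obj_center, cfg.object_diameter_mm / 2)

    values = cfg.air_hu + (cfg.background_hu - cfg.air_hu) * body + cfg.contrast_hu * obj
    if cfg.draw_small_cylinders:
        for i, d in enumerate(SMALL_CYLINDER_DIAMETERS_MM):
            angle = cfg.object_angle_deg + 60.0 + 25.0 * i
            theta = np.radians(angle)
            c = (
                phantom_center[0] + cfg.object_radius_mm * float(np.sin(theta)),
                phantom_center[1] - cfg.object_radius_mm * float(np.cos(theta)),
            )
            values = values + cfg.contrast_hu * _disc_coverage(n, sp, c, d / 2)

    if cfg.noise_sd_hu > 0:
        rng = np.random.default_rng(slice_seed)
        noise = rng.normal(0.0, cfg.noise_sd_hu, size=values.shape)
        values = values + noise * (body > 0)

    truth = GroundTruth(
        object_center_mm=obj_center,
        object_angle_deg=cfg.object_angle_deg % 360.0,
        phantom_center_mm=phantom_center,
        true_contrast_hu=cfg.contrast_hu,
        true_noise_sd_hu=cfg.noise_sd_hu,
    )
    return HUImage(values, (sp, sp)), truth


def generate_stack(cfg: SyntheticPhantomConfig) -> list[tuple[HUImage, GroundTruth]]:
    """Render ``cfg.n_slices`` independent slices with derived seeds."""
    return [
        generate_slice(cfg, derive_slice_seed(cfg.seed, k)) for k in range(cfg.n_slices)
    ]


def write_synthetic_dicom(stack, directory) -> list[str]:
    """Write a stack as minimal single-frame CT DICOM files.

    HU are stored as unsigned 16-bit integers with RescaleSlope 1 and
    RescaleIntercept −1024, so re-loading recovers HU to within the ±0.5
    integer rounding.  Instance numbers run 1..n in stack order.
    """
    os.makedirs(directory, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for k, item in enumerate(stack):
        image = item[0] if isinstance(item, tuple) else item
        intercept = -1024.0
        stored = np.clip(np.round(image.values - intercept), 0, 65535).astype(np.uint16)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = series_uid
        ds.Modality = "CT"
        ds.PatientName = "SYNTHETIC^PHANTOM"
        ds.PatientID = "SYNTH"
        ds.ContentDate = datetime.date.today().strftime("%Y%m%d")
        ds.InstanceNumber = k + 1
        ds.SliceLocation = float(k)
        ds.Rows, ds.Columns = image.rows, image.cols
        ds.PixelSpacing = [image.spacing_mm[0], image.spacing_mm[1]]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = stored.tobytes()
        path = os.path.join(directory, f"slice_{k + 1:03d}.dcm")
        pydicom.dcmwrite(path, ds, enforce_file_format=True)
        paths.append(path)
    return paths


def config_with(cfg: SyntheticPhantomConfig, **changes) -> SyntheticPhantomConfig:
    """Convenience: a copy of ``cfg`` with the given fields replaced."""
    return replace(cfg, **changes)
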
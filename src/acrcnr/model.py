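"""Model/Results front-end for batch measurement.

`PhantomCNR` wraps a stack of slices plus a search configuration; `fit()`
runs the automatic measurement on every slice and returns
`PhantomCNRResults`, which carries per-slice CNR results, their mean ± SD
summary, diagnostics (centroids, detected angles, angular profiles) and a
text `summary()` table.  Plotting hangs off the results object.

This is a convenience layer: the functional API in :mod:`acrcnr.core`
(``auto_cnr`` and friends) does the actual work and can be used directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AutoCNROutcome, SearchConfig, auto_cnr, measure_cnr
from .errors import ValidationError
from .image import HUImage, image_from_array, load_dicom_stack
from .report import (
    ACR_CNR_TOLERANCE,
    MeasurementSeries,
    acr_tolerance_check,
    summarize,
    write_series_csv,
)


class PhantomCNR:
    """Automatic CNR measurement model for a stack of phantom slices.

    Parameters
    ----------
    images : sequence of HUImage
        The slices to measure (one is fine).
    config : SearchConfig, optional
        Rotating-ROI search geometry; defaults to the 55 mm / 25 mm / 2°
        method parameters.
    label : str
        Condition label carried into reports (e.g. ``"120 kV"``).
    """

    def __init__(self, images, config: SearchConfig | None = None, label: str = ""):
        images = list(images)
        if not images:
            raise ValidationError("need at least one slice")
        for im in images:
            if not isinstance(im, HUImage):
                raise ValidationError("all inputs must be HUImage instances")
        self.images = images
        self.config = config or SearchConfig()
        self.label = label

    @classmethod
    def from_dicom_dir(cls, directory, config: SearchConfig | None = None, label: str = ""):
        """Build a model from a directory of single-frame CT DICOM files."""
        return cls(load_dicom_stack(directory), config=config, label=label)

    @classmethod
    def from_arrays(cls, arrays, spacing_mm, config: SearchConfig | None = None, label: str = ""):
        """Build a model from raw HU arrays sharing one pixel spacing."""
        return cls(
            [image_from_array(a, spacing_mm) for a in arrays],
            config=config,
            label=label,
        )

    def fit(self) -> "PhantomCNRResults":
        """Run the automatic measurement on every slice."""
        outcomes = [auto_cnr(im, self.config) for im in self.images]
        return PhantomCNRResults(self, tuple(outcomes))

    def fit_manual(self, object_center_mm, background_center_mm) -> "PhantomCNRResults":
        """Measure with user-supplied ROI centers (the manual workflow),
        skipping segmentation and localization."""
        outcomes = []
        for im in self.images:
            res = measure_cnr(im, object_center_mm, background_center_mm, self.config)
            outcomes.append(
                AutoCNROutcome(
                    result=res,
                    location=None,
                    centroid=None,
                    profile=None,
                    warnings=("manual ROI placement: localization skipped",),
                )
            )
        return PhantomCNRResults(self, tuple(outcomes))


@dataclass(frozen=True)
class PhantomCNRResults:
    """Fitted results: per-slice measurements plus summary statistics."""

    model: PhantomCNR
    outcomes: tuple[AutoCNROutcome, ...]

    @property
    def per_slice(self):
        return [o.result for o in self.outcomes]

    @property
    def series(self) -> MeasurementSeries:
        return summarize(self.per_slice, label=self.model.label)

    @property
    def mean_cnr(self) -> float:
        return self.series.mean_cnr

    @property
    def detected_angles_deg(self) -> list[float]:
        return [o.location.angle_deg for o in self.outcomes if o.location is not None]

    @property
    def tolerance_pass(self) -> bool:
        return acr_tolerance_check(self.series)

    def to_frame(self) -> pd.DataFrame:
        """Per-slice table with localization diagnostics."""
        rows = []
        for k, o in enumerate(self.outcomes):
            r = o.result
            rows.append(
                {
                    "slice": k + 1,
                    "contrast_hu": r.contrast_hu,
                    "noise_hu": r.noise_hu,
                    "cnr": r.cnr,
                    "angle_deg": o.location.angle_deg if o.location else np.nan,
                    "centroid_x_mm": o.centroid.center_mm[0] if o.centroid else np.nan,
                    "centroid_y_mm": o.centroid.center_mm[1] if o.centroid else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def save_csv(self, path) -> None:
        write_series_csv(self.series, path)

    def summary(self) -> str:
        s = self.series
        cfg = self.model.config
        lines = [
            "Automatic CNR measurement" + (f" — {s.label}" if s.label else ""),
            "=" * 60,
            f"slices: {s.n}    search: radius {cfg.radius_mm:g} mm, "
            f"ROI {cfg.roi_diameter_mm:g} mm, step {cfg.step_deg:g} deg, "
            f"background ROI {cfg.background_roi_diameter_mm:g} mm",
            "-" * 60,
            f"{'':<14}{'mean':>10}{'sd':>10}",
            f"{'contrast (HU)':<14}{s.mean_contrast:>10.1f}{s.sd_contrast:>10.1f}",
            f"{'noise (HU)':<14}{s.mean_noise:>10.1f}{s.sd_noise:>10.1f}",
            f"{'CNR':<14}{s.mean_cnr:>10.1f}{s.sd_cnr:>10.1f}",
            "-" * 60,
            f"tolerance (CNR >= {ACR_CNR_TOLERANCE:g}): "
            + ("PASS" if self.tolerance_pass else "FAIL"),
        ]
        angles = self.detected_angles_deg
        if angles:
            lines.append(
                f"detected object angle: {np.mean(angles):.1f} deg "
                f"(sd {np.std(angles):.2f})"
            )
        for o in self.outcomes:
            for w in o.warnings:
                if f"warning: {w}" not in lines:
                    lines.append(f"warning: {w}")
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_profile(self, slice_index: int = 0, ax=None):
        """Angular profile of one slice with the detected angle marked."""
        import matplotlib.pyplot as plt

        o = self.outcomes[slice_index]
        if o.profile is None:
            raise ValidationError("no angular profile (manual measurement)")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(o.profile.angles_deg, o.profile.mean_hu, lw=1)
        ax.axvline(o.location.angle_deg, color="r", ls="--", lw=1,
                   label=f"detected {o.location.angle_deg:.0f}°")
        ax.set_xlabel("ROI angle (deg, clockwise from 12 o'clock)")
        ax.set_ylabel("mean CT number (HU)")
        ax.legend()
        return ax

    def plot_overlay(self, slice_index: int = 0, ax=None):
        """Slice with the background and detected object ROIs drawn."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Circle

        o = self.outcomes[slice_index]
        im = self.model.images[slice_index]
        cfg = self.model.config
        if ax is None:
            _, ax = plt.subplots()
        extent = (
            -im.spacing_mm[1] / 2, im.width_mm - im.spacing_mm[1] / 2,
            im.height_mm - im.spacing_mm[0] / 2, -im.spacing_mm[0] / 2,
        )
        ax.imshow(im.values, cmap="gray", extent=extent, vmin=0, vmax=150)
        if o.centroid is not None:
            ax.add_patch(Circle(o.centroid.center_mm,
                                cfg.background_roi_diameter_mm / 2,
                                fill=False, color="c", lw=1.2))
        if o.location is not None:
            ax.add_patch(Circle(o.location.center_mm, cfg.roi_diameter_mm / 2,
                                fill=False, color="r", lw=1.2))
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        return ax
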
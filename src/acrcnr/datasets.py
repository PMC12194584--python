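"""Published summary measurements for the ACR phantom low-contrast module.

Mean ± SD of contrast and noise (HU) measured on a GE Revolution 128
scanner with filtered back-projection, for manual and automatic ROI
placement, across sweeps of tube voltage, tube current, slice thickness,
reconstruction FOV and convolution kernel.  These are the worked-example
inputs for the Eq.-style CNR arithmetic: CNR = mean contrast / mean noise.

Use :func:`load_reference_measurements` for a tidy DataFrame and
:func:`reference_cnr` for one cell's CNR at the table's printed rounding.
"""

from __future__ import annotations

import pandas as pd

# (sweep, setting, method, contrast_mean, contrast_sd, noise_mean, noise_sd)
_RECORDS = [
    ("tube_voltage", "80 kV", "manual", 5.1, 2.1, 4.3, 0.1),
    ("tube_voltage", "80 kV", "automatic", 5.1, 0.3, 4.2, 0.0),
    ("tube_voltage", "100 kV", "manual", 6.8, 0.5, 3.6, 0.1),
    ("tube_voltage", "100 kV", "automatic", 7.2, 0.6, 3.6, 0.1),
    ("tube_voltage", "120 kV", "manual", 6.4, 0.2, 3.0, 0.1),
    ("tube_voltage", "120 kV", "automatic", 6.4, 0.1, 2.9, 0.2),
    ("tube_voltage", "140 kV", "manual", 6.8, 0.5, 2.7, 0.1),
    ("tube_voltage", "140 kV", "automatic", 7.3, 0.5, 2.7, 0.1),
    ("tube_current", "80 mA", "manual", 6.2, 0.5, 4.3, 0.2),
    ("tube_current", "80 mA", "automatic", 6.4, 0.6, 4.3, 0.2),
    ("tube_current", "100 mA", "manual", 7.2, 0.3, 3.9, 0.2),
    ("tube_current", "100 mA", "automatic", 6.7, 0.7, 3.9, 0.1),
    ("tube_current", "120 mA", "manual", 6.6, 0.5, 3.7, 0.1),
    ("tube_current", "120 mA", "automatic", 6.9, 0.8, 4.4, 1.4),
    ("tube_current", "140 mA", "manual", 6.2, 0.2, 3.2, 0.2),
    ("tube_current", "140 mA", "automatic", 6.6, 0.4, 3.2, 0.0),
    ("tube_current", "160 mA", "manual", 6.3, 0.3, 3.0, 0.1),
    ("tube_current", "160 mA", "automatic", 6.4, 0.1, 2.9, 0.2),
    ("tube_current", "200 mA", "manual", 6.6, 0.3, 2.7, 0.1),
    ("tube_current", "200 mA", "automatic", 6.6, 0.3, 2.7, 0.1),
    ("slice_thickness", "1.25 mm", "manual", 6.3, 2.1, 5.1, 0.1),
    ("slice_thickness", "1.25 mm", "automatic", 6.9, 2.1, 5.0, 0.2),
    ("slice_thickness", "3 mm", "manual", 6.6, 0.5, 3.3, 0.1),
    ("slice_thickness", "3 mm", "automatic", 6.7, 0.4, 3.2, 0.1),
    ("slice_thickness", "5 mm", "manual", 7.3, 0.8, 2.6, 0.1),
    ("slice_thickness", "5 mm", "automatic", 7.4, 0.8, 2.6, 0.0),
    ("slice_thickness", "7 mm", "manual", 6.9, 0.5, 2.7, 0.1),
    ("slice_thickness", "7 mm", "automatic", 6.8, 0.6, 2.7, 0.1),
    ("slice_thickness", "9 mm", "manual", 7.1, 0.6, 2.3, 0.1),
    ("slice_thickness", "9 mm", "automatic", 7.2, 0.6, 2.3, 0.1),
    ("fov", "190 mm", "manual", 6.4, 0.4, 2.5, 0.1),
    ("fov", "190 mm", "automatic", 5.9, 0.3, 2.5, 0.1),
    ("fov", "200 mm", "manual", 7.0, 0.7, 2.4, 0.1),
    ("fov", "200 mm", "automatic", 7.0, 0.6, 2.4, 0.1),
    ("fov", "210 mm", "manual", 6.6, 0.3, 2.5, 0.0),
    ("fov", "210 mm", "automatic", 6.8, 0.1, 2.5, 0.0),
    ("fov", "220 mm", "manual", 7.2, 0.6, 2.5, 0.2),
    ("fov", "220 mm", "automatic", 7.2, 0.7, 2.4, 0.1),
    ("fov", "230 mm", "manual", 6.5, 0.2, 2.4, 0.1),
    ("fov", "230 mm", "automatic", 6.7, 0.2, 2.4, 0.1),
    ("kernel", "edge", "manual", 6.5, 1.3, 50.7, 0.9),
    ("kernel", "edge", "automatic", 5.9, 2.0, 50.1, 1.9),
    ("kernel", "ultra", "manual", 6.0, 1.1, 35.3, 0.2),
    ("kernel", "ultra", "automatic", 5.5, 2.0, 35.1, 0.6),
    ("kernel", "lung", "manual", 6.8, 0.6, 28.8, 1.5),
    ("kernel", "lung", "automatic", 6.8, 2.1, 28.4, 0.7),
    ("kernel", "bone", "manual", 6.9, 1.6, 23.4, 0.4),
    ("kernel", "bone", "automatic", 7.4, 0.3, 23.3, 0.6),
    ("kernel", "chest", "manual", 6.8, 0.7, 6.1, 0.1),
    ("kernel", "chest", "automatic", 6.5, 0.6, 6.1, 0.1),
    ("kernel", "standard", "manual", 6.2, 0.3, 3.0, 0.1),
    ("kernel", "standard", "automatic", 6.4, 0.1, 2.9, 0.2),
]

_COLUMNS = [
    "sweep", "setting", "method",
    "contrast_mean_hu", "contrast_sd_hu", "noise_mean_hu", "noise_sd_hu",
]


def load_reference_measurements() -> pd.DataFrame:
    """Tidy DataFrame of the published mean ± SD contrast/noise values."""
    return pd.DataFrame(_RECORDS, columns=_COLUMNS)


def reference_cnr(sweep: str, setting: str, method: str, decimals: int = 1) -> float:
    """CNR = mean contrast / mean noise for one published cell, rounded to
    the precision the summary figures are quoted at (1 decimal)."""
    df = load_reference_measurements()
    row = df[(df.sweep == sweep) & (df.setting == setting) & (df.method == method)]
    if row.empty:
        raise KeyError(f"no reference cell for ({sweep}, {setting}, {method})")
    cnr = float(row.contrast_mean_hu.iloc[0] / row.noise_mean_hu.iloc[0])
    return round(cnr, decimals)
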
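"""Exception hierarchy for the measurement pipeline.

Every stage of the automatic measurement raises a distinct exception type so
that batch drivers and the CLI can map failures to exit codes
(2 = phantom not found, 3 = degenerate statistics, 4 = I/O).
"""


class AcrCnrError(Exception):
    """Base class for all package errors."""


class CalibrationError(AcrCnrError):
    """A DICOM slice is missing an attribute needed to recover HU values
    or physical geometry (pixel data, pixel spacing, monochrome photometry)."""


class ValidationError(AcrCnrError):
    """An in-memory input violates a structural contract (ragged array,
    non-positive spacing, undersized matrix)."""


class PhantomNotFoundError(AcrCnrError):
    """Thresholding produced no foreground: the image contains no phantom."""


class GeometryError(AcrCnrError):
    """A requested ROI does not fit inside the image."""


class StatisticsError(AcrCnrError):
    """An ROI selects too few pixels for mean/SD computation."""


class DegenerateStatisticsError(AcrCnrError):
    """Background SD is zero: noiseless image; CNR undefined."""


class ConfigError(AcrCnrError):
    """A synthetic-phantom configuration violates its invariants."""
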
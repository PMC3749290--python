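"""Exception hierarchy for the densitometry pipeline.

Every stage raises a subclass of :class:`LungDensError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class LungDensError(Exception):
    """Base class for all pipeline errors."""


class VolumeFormatError(LungDensError):
    """A file could not be parsed as the requested image format."""


class CalibrationMetadataError(LungDensError):
    """HU rescale metadata (slope/intercept) is missing from a DICOM series."""


class GeometryError(LungDensError):
    """Image grids disagree (shape/spacing) or a DICOM series is inconsistent."""


class DegenerateInputError(LungDensError):
    """An operation received an empty or otherwise degenerate region."""


class SeedNotFoundError(LungDensError):
    """No trachea-like seed could be located for airway region growing."""


class SegmentationError(LungDensError):
    """Lung segmentation failed to retain any plausible lung component."""


class GenerationError(LungDensError):
    """A synthetic-data spec is infeasible (e.g. unreachable lesion fraction)."""


class ParameterError(LungDensError):
    """An operation parameter is outside its valid domain."""


class DataError(LungDensError):
    """A cohort table lacks the data required for a statistical operation."""
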
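"""Exception hierarchy for the screen-analysis pipeline."""


class LpscreenError(Exception):
    """Base class for all package errors."""


class ScreenSchemaError(LpscreenError):
    """A required column is missing or malformed in a well table."""


class WellTableParseError(LpscreenError):
    """A numeric field of a non-empty well could not be parsed."""


class DuplicateWellError(LpscreenError):
    """The same (plate, well, readout) appears more than once."""


class LayoutCapacityError(LpscreenError):
    """Requested control wells do not fit in the reserved plate region."""


class LayoutValidationError(LpscreenError):
    """A plate layout violates the design invariants."""


class NormalizationError(LpscreenError):
    """Plate median is non-positive; percent-of-median is undefined."""


class ControlCoverageError(LpscreenError):
    """Too few wells of the required role to anchor a statistic."""


class DegeneratePlateError(LpscreenError):
    """Plate has zero spread; z-scores are undefined."""


class QcError(LpscreenError):
    """A QC statistic is undefined for the given inputs."""


class BackgroundUndefinedError(LpscreenError):
    """No inter-cell pixels remain to estimate image background from."""


class OvercrowdedFieldError(LpscreenError):
    """Requested synthetic cells do not fit in the field with clearance."""
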
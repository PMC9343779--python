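"""Exception hierarchy shared across the platescan modules."""


class PlatescanError(Exception):
    """Base class for all platescan-specific errors."""


class MaskFormatError(PlatescanError):
    """The image-mask CSV is malformed (bad header, duplicate or invalid labels, negative geometry)."""


class MaskBoundsError(PlatescanError):
    """A mask rectangle falls outside the plate image bounds."""

    def __init__(self, label: str, message: str | None = None):
        self.label = label
        super().__init__(message or f"mask rectangle for well {label!r} lies outside the image bounds")


class LevelFormatError(PlatescanError):
    """The classification-levels CSV does not define a contiguous partition of [0, inf)."""


class TrainingDataError(PlatescanError):
    """Training images are missing or insufficient for one or more levels."""


class ModelStateError(PlatescanError):
    """The classifier is not trained / not in a usable state."""


class SpreadsheetFormatError(PlatescanError):
    """An OD spreadsheet cell could not be parsed."""


class MatchError(PlatescanError):
    """A well label could not be matched against the OD grid."""


class EmptyEvaluationError(PlatescanError):
    """Model evaluation was requested with zero (image, OD) pairs."""


class SchemaError(PlatescanError):
    """A session JSON file has an unknown schema version or violates its invariants."""


class InsufficientDataError(PlatescanError):
    """Too few valid timepoints for the requested curve computation."""


class UnderdeterminedError(PlatescanError):
    """Too few distinct doses to identify the dose-response parameters."""


class DegenerateFitWarning(UserWarning):
    """The data carry no usable signal for the fit (e.g. a flat curve); best-effort parameters returned."""
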
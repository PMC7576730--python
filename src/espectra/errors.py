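"""Exception hierarchy for the espectra package."""


class EspectraError(Exception):
    """Base class for all package errors."""


class CurveFormatError(EspectraError):
    """The file layout does not match the declared dialect (missing columns, bad delimiter)."""


class CurveParseError(EspectraError):
    """A data row could not be parsed as numbers.

    Carries the 1-based row index of the offending line when known.
    """

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class MetadataError(EspectraError):
    """Required acquisition metadata (probe radius, spring constant) is missing or invalid."""


class ValidationError(EspectraError):
    """An input object violates a documented invariant."""


class ConfigError(EspectraError):
    """A configuration value is inconsistent with the data (e.g. window larger than curve)."""


class ContactPointNotFoundError(EspectraError):
    """No ratio-of-variances peak above the prominence threshold: contact cannot be located."""


class EmptyCurveError(EspectraError):
    """All samples fall before the contact point; no indentation data remains."""


class FitError(EspectraError):
    """A least-squares fit failed to converge or produced a non-physical optimum."""


class CalibrationError(EspectraError):
    """The decay-factor calibration is degenerate (e.g. zero modulus contrast)."""


class SurrogateUnavailableError(EspectraError):
    """The layered-contact polynomial surrogate coefficients are not bundled.

    The self-consistent exponential bilayer generator
    (:func:`espectra.synthdata.generate_bilayer`) is the available numerical
    reference for calibration and recovery studies.
    """
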
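"""Exception hierarchy for the Leg Agility scoring pipeline."""


class LegAgilityError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LegAgilityError):
    """A file or table does not match the expected schema."""


class TooShortError(LegAgilityError):
    """A recording has too few usable samples for analysis."""


class ManifestError(LegAgilityError):
    """A cohort manifest violates its invariants."""


class CalibrationError(LegAgilityError):
    """Gravity-alignment recalibration could not be performed."""


class DegenerateSpectrumError(LegAgilityError):
    """The signal is constant: no meaningful spectrum exists."""


class ChannelError(LegAgilityError):
    """A required signal channel is absent from a recording."""


class ValidationError(LegAgilityError):
    """A cross-validation setup is invalid (e.g. a single subject)."""


class TrainingError(LegAgilityError):
    """Model training diverged or failed."""


class SchemaError(LegAgilityError):
    """A model artifact is incompatible with the given feature schema."""
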
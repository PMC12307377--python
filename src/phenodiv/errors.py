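"""Exception hierarchy for phenodiv.

All package errors derive from :class:`PhenodivError` so callers can catch
one base class at pipeline boundaries.
"""


class PhenodivError(Exception):
    """Base class for all phenodiv errors."""


class SchemaError(PhenodivError):
    """Input table structure does not match the trait registry."""


class TableParseError(PhenodivError):
    """A cell could not be parsed; message carries row/column location."""


class ValidationError(PhenodivError):
    """A value violates a trait's allowed code set or sign constraint."""


class InsufficientDataError(PhenodivError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(PhenodivError):
    """Statistic is mathematically undefined for this input (e.g. CV at zero mean)."""


class DegenerateTraitError(PhenodivError):
    """A trait has zero variance where variation is required."""


class ConfigurationError(PhenodivError):
    """Invalid user configuration (spec file, correlation matrix, knobs)."""


class AlignmentError(PhenodivError):
    """Trait or accession ordering mismatch between two pipeline objects."""
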
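"""Exception hierarchy.

Validation failures (bad input files, contract violations a user can fix)
derive from :class:`ValidationError`; the CLI maps those to exit code 2 and
everything else to exit code 1.
"""


class BarcodiagError(Exception):
    """Base class for all package errors."""


class ValidationError(BarcodiagError):
    """User-correctable input or parameter problem (CLI exit code 2)."""


class FormatError(ValidationError):
    """Malformed sequence or table file; names the offending record/offset."""


class DuplicateIdError(FormatError):
    """Record identifier occurs more than once within one file."""


class EmptyInputError(FormatError):
    """A file that must contain at least one record contains none."""


class AlignmentLengthError(FormatError):
    """Alignment rows of unequal length; message lists the offending ids."""


class ContractError(ValidationError):
    """An operation was called outside its stated preconditions."""


class UnknownSpeciesError(ValidationError):
    """A species label was requested that the panel/alignment does not carry."""


class InsufficientDataError(ValidationError):
    """Too few rows/species for the requested statistic."""


class UndefinedValueError(ValidationError):
    """The requested quantity is undefined on this input (e.g. all-gap GC)."""


class NoPrimerError(BarcodiagError):
    """No primer satisfying the design constraints exists at this site."""


class SaturationError(BarcodiagError):
    """K2P distance undefined: a logarithm argument is non-positive."""


class MissingOverlapError(BarcodiagError):
    """A taxon pair shares no comparable (unambiguous, non-gap) column."""


class ParameterError(ValidationError):
    """Inconsistent simulation or design parameters."""
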
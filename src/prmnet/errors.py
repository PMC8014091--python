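"""Exception types shared across the pipeline."""


class PrmnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PrmnetError):
    """Invalid configuration value or combination."""


class FormatError(PrmnetError):
    """Malformed input file (missing columns, bad dialect)."""


class ValidationError(PrmnetError):
    """Well-formed input with invalid content (e.g. negative area)."""


class InsufficientDataError(PrmnetError):
    """Too few observations to carry out the requested computation."""


class MappingError(PrmnetError):
    """An identifier could not be mapped (peptide->entity, sample->injection)."""


class OrderingError(PrmnetError):
    """Pipeline stage invoked out of order (e.g. log2 before imputation)."""


class DegenerateDataError(PrmnetError):
    """Input degenerate for the statistic (zero mean, constant vector...)."""


class IntegrityError(PrmnetError):
    """A cached intermediate file does not match its recorded checksum."""
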
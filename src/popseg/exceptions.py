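"""Exception hierarchy shared across the package."""


class PopsegError(Exception):
    """Base class for all package errors."""


class FormatError(PopsegError):
    """A delimited input file could not be parsed or lacks required columns."""


class IntegrityError(PopsegError):
    """Referential integrity violated (duplicate or orphan subject ids)."""


class ValidationError(PopsegError):
    """Strict-mode validation failure; names the offending row and column."""


class CompletenessError(PopsegError):
    """An operation requiring full coverage (e.g. one assignment per subject
    per scheme) received incomplete inputs."""


class MappingError(PopsegError):
    """A condition code is absent from the condition map."""


class DomainError(PopsegError):
    """An input value lies outside the operation's domain."""


class DegenerateTableError(PopsegError):
    """A contingency table unsuitable for a chi-squared test (fewer than two
    non-empty segments, or a zero expected count)."""


class ParameterError(PopsegError):
    """Invalid generator parameters (probability outside [0, 1], negative
    severity slope on an adverse feature, ...)."""
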
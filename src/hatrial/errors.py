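"""Exception hierarchy used across the package.

All package errors derive from :class:`HatrialError` so callers can catch
package failures with one handler while still distinguishing user-input
problems (format/validation) from mathematical domain violations.
"""


class HatrialError(Exception):
    """Base class for all package errors."""


class FormatError(HatrialError):
    """A file does not conform to the expected tabular layout."""


class ParseError(FormatError):
    """A row or cell could not be parsed; message carries the line number."""


class ValidationError(HatrialError):
    """Parsed data violates a declared invariant (duplicates, unknown keys, ...)."""


class InsufficientReplicationError(ValidationError):
    """A group has too few observations for the requested inference."""


class CoverageError(ValidationError):
    """A required indicator is missing for one or more groups."""


class DomainError(HatrialError, ValueError):
    """Input is outside the mathematical domain of an operation."""


class DegenerateInputError(DomainError):
    """Input is formally valid but degenerate (all-zero counts, constant vector)."""


class ConfigError(HatrialError):
    """A run or simulation configuration is contradictory or invalid."""
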
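"""Exception hierarchy.

Exit-code mapping used by the command-line layer:
parse/input problems -> 2, cross-reference problems -> 3, configuration -> 4.
"""


class BhlhkitError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(BhlhkitError):
    """Malformed or empty input data."""

    exit_code = 2


class AlignmentShapeError(InputError):
    """Reference alignment rows are not rectangular or are too few."""


class AlphabetError(InputError):
    """Sequence contains characters outside the declared alphabet."""


class DataError(InputError):
    """Numeric data violates its contract (e.g. negative RPKM)."""


class ModelError(InputError):
    """Gene model violates its contract (e.g. CDS length not divisible by 3)."""


class CoordinateError(InputError):
    """Genomic or protein coordinates out of range."""


class MappingError(InputError):
    """A domain lacks the canonical column mapping an operation requires."""


class ConsistencyError(BhlhkitError):
    """Cross-referenced inputs disagree (orphan ids, mismatched profiles)."""

    exit_code = 3


class ConfigError(BhlhkitError):
    """Invalid configuration value."""

    exit_code = 4


class GenerationError(BhlhkitError):
    """A synthetic-data request is infeasible as stated."""
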
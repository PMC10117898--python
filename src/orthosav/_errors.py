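"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`OrthosavError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.  Configuration/usage problems map to exit
code 2 at the CLI, everything else to 1.
"""


class OrthosavError(Exception):
    """Base class for all orthosav errors."""


class FormatError(OrthosavError):
    """A file could not be parsed in the expected format."""


class ValidationError(OrthosavError):
    """Parsed content violates a domain invariant (bad residue, AF > 1, ...)."""


class ConsistencyError(OrthosavError):
    """Inputs disagree with each other (e.g. variant ref != sequence residue)."""


class DimensionError(OrthosavError):
    """Array/table shapes do not match."""


class NumberingError(OrthosavError):
    """A coordinate conversion left the valid position range."""


class IntegrityError(OrthosavError):
    """Duplicate or contradictory rows in a table."""


class ConfigError(OrthosavError):
    """Invalid configuration (unknown predictor, infeasible margins, ...)."""


class BackendError(OrthosavError):
    """A probability backend failed; distinct from input validation errors."""


class UndefinedMetricError(OrthosavError):
    """A statistic is undefined for the given input (one-class labels, zero variance)."""
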
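"""Exception hierarchy for the trawlniche package.

Distinct classes let the CLI map failures onto distinct exit codes:
input problems, configuration problems, and computation problems.
"""


class TrawlnicheError(Exception):
    """Base class for all package errors."""


class InputError(TrawlnicheError):
    """An input file is missing or unreadable."""


class SchemaError(InputError):
    """A required column is missing or a table cannot be interpreted."""


class ConfigError(TrawlnicheError):
    """An invalid option, mode name, or parameter value."""


class ComputationError(TrawlnicheError):
    """Base class for statistical/numerical failures."""


class DegenerateWeightError(ComputationError):
    """All weights are zero (or negative) where positive mass is required."""


class NoCatchError(ComputationError):
    """A catch-weighted statistic was requested but total catch is zero."""


class MissingDataError(ComputationError):
    """No valid observations remain after missing-value exclusion."""


class InsufficientDataError(ComputationError):
    """Too few observations for the requested fit or summary."""


class DegenerateDataError(ComputationError):
    """Data carry no information for the fit (e.g. a single maturity class)."""


class InvalidFitError(ComputationError):
    """A downstream operation was applied to an unconverged fit."""


class UnstableFitError(ComputationError):
    """Resampling procedure failed on more than half of its replicates."""


class EmptySubgroupError(ComputationError):
    """A subgroup predicate selected no individuals."""


class UndefinedVariableError(ComputationError):
    """A variable absent from a summary was requested."""
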
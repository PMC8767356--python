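"""Exception hierarchy shared across the package."""


class FittreeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FittreeError, ValueError):
    """A value violates a mathematical precondition (empty distribution, zero mass, ...)."""


class PartitionConsistencyError(DomainError):
    """Class totals of a partition disagree with the parent distribution."""


class DegenerateSplitError(FittreeError):
    """Split information is (numerically) zero; the candidate must be rejected, not ranked."""


class ConfigError(FittreeError, ValueError):
    """A configuration document (cost matrix, standard, cohort spec) is invalid."""


class MissingStandardError(ConfigError, LookupError):
    """No scoring bands are defined for the requested (grade, gender) stratum."""


class InputError(FittreeError, ValueError):
    """A caller-supplied record or table fails validation."""


class TreeFormatError(FittreeError, ValueError):
    """A serialized tree document violates the schema."""
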
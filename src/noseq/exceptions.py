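"""Exception hierarchy shared across the package."""


class NoseqError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(NoseqError):
    """A file does not conform to its declared format (FASTA/FASTQ/TSV)."""


class ValidationError(NoseqError):
    """Input values violate a documented precondition or invariant."""


class ConfigurationError(NoseqError):
    """A configuration value (preset name, path, parameter) is unusable."""


class DegenerateDistributionError(NoseqError):
    """All A rates are identical: the z-statistic is undefined (sigma == 0)."""


class EmptyInputError(NoseqError):
    """An operation that needs at least one record received none."""
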
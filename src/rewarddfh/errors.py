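"""Exception hierarchy.

Validation failures (malformed tables, bad configuration) and statistical
degeneracies (constant columns, single-class fits, empty groups) are kept
distinct so the command-line layer can map them to different exit codes.
"""


class RewardDFHError(Exception):
    """Base class for all package errors."""


class ValidationError(RewardDFHError):
    """A table, configuration, or argument violates its contract."""


class ConfigError(ValidationError):
    """A simulation or run configuration is invalid."""


class DegenerateDataError(RewardDFHError):
    """The data are statistically degenerate for the requested operation
    (constant feature, single class, empty group, zero-variance norms)."""


class ConvergenceError(RewardDFHError):
    """An iterative fit failed to converge within its iteration budget."""
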
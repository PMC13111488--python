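"""Exception hierarchy for input validation.

Every validation failure names the offending field so that configuration
and parameter-table errors are actionable from the command line.
"""


class ValidationError(ValueError):
    """Base class for all model-input validation failures."""


class ProbabilityRangeError(ValidationError):
    """A probability lies outside [0, 1]."""


class SimplexViolationError(ValidationError):
    """An outcome-probability triple does not sum to one."""


class NegativeCostError(ValidationError):
    """A cost or cost component is negative."""


class BaselineConsistencyError(ValidationError):
    """A baseline arm is not modelled as certain success."""


class CalibrationError(ValidationError):
    """A Dirichlet dispersion target is infeasible or the centre is degenerate."""


class ConfigError(ValidationError):
    """An analysis configuration file is malformed."""
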
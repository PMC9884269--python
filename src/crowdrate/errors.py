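"""Exception hierarchy shared across the package.

Exit-code contract for the CLI: configuration problems map to exit code 2,
data problems to exit code 3 (see :mod:`crowdrate.cli`).
"""


class CrowdRateError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CrowdRateError, ValueError):
    """A parameter violates a model or scenario invariant."""


class ConfigError(CrowdRateError):
    """A configuration file failed to parse or validate."""


class MissingDataError(CrowdRateError):
    """An estimator was asked for a quantity the data cannot support."""


class DecisionSchemaError(CrowdRateError):
    """A decisions table does not match the documented column schema."""
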
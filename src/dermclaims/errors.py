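"""Exception hierarchy for the dermclaims pipeline.

Exit-code mapping for the CLI: ConfigError -> 2, SchemaError -> 3,
anything else -> 1.
"""


class DermClaimsError(Exception):
    """Base class for all package errors."""


class ConfigError(DermClaimsError, ValueError):
    """Invalid configuration (probabilities, costs, ratios...)."""


class SchemaError(DermClaimsError, ValueError):
    """Input table violates the documented schema; names row and column."""


class DomainError(DermClaimsError, ValueError):
    """Input outside an operation's domain (e.g. age < 18, zero persons)."""


class GeneratorError(DermClaimsError, RuntimeError):
    """Synthetic generator could not satisfy its postconditions."""


class CalibrationError(DermClaimsError, RuntimeError):
    """Detection-cascade calibration is infeasible for the given inputs."""
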
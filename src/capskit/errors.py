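"""Exception hierarchy.

ValidationError / ConfigError map to CLI exit code 1 (bad input or
configuration); ComputationError maps to exit code 2 (the computation
itself failed, e.g. a fit did not converge).
"""


class CapskitError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(CapskitError):
    """Invalid user input: malformed file, bad schema, impossible request."""


class ConfigError(ValidationError):
    """Invalid configuration value (enzyme motif, unknown key, ...)."""


class ComputationError(CapskitError):
    """A computation failed on valid input (no exponential phase, no fit)."""
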
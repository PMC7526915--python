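"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit 2, I/O problems
exit 3 (see :mod:`ticpr.cli`).
"""


class TicprError(Exception):
    """Base class for all package errors."""


class ValidationError(TicprError, ValueError):
    """Input data violates a documented contract (bad CSV, bad annotation...)."""


class ConfigurationError(TicprError, ValueError):
    """A configuration value is out of its legal range."""


class GenerationError(TicprError, ValueError):
    """A synthetic-episode scenario is infeasible as specified."""
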
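"""Exception hierarchy.

Missing values are never signalled by exceptions: scalar APIs return ``None``
and table APIs use NaN. Exceptions are reserved for contract violations.
"""


class SimscoreError(Exception):
    """Base class for all package errors."""


class DomainError(SimscoreError, ValueError):
    """An input violates a mathematical/physiological precondition
    (non-positive measurement, unknown sex, badly ordered quartiles, ...)."""


class ConfigError(SimscoreError, ValueError):
    """A generator or pipeline configuration is invalid."""


class FormatError(SimscoreError, ValueError):
    """A cohort file does not conform to the CSV dialect."""
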
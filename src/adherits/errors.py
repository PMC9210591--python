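"""Exception hierarchy shared across the pipeline.

Each stage raises a subclass of :class:`AdheritsError` so the command-line
driver can map failures to distinct exit codes (validation vs convergence
vs I/O).
"""


class AdheritsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AdheritsError, ValueError):
    """Malformed input data or an invalid configuration value."""


class CohortInvariantError(ValidationError):
    """A patient record violates a cohort invariant.

    Example: a death date on or before the discharge date, which would make
    the adherence observation window empty.
    """


class ConvergenceError(AdheritsError, RuntimeError):
    """Model estimation failed (singular design, optimizer failure)."""
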
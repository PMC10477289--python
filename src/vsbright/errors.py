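"""Exception hierarchy.

Everything user-facing derives from :class:`VsbrightError` so callers can
catch one base class; the concrete subclasses also derive from the closest
builtin (``ValueError``/``RuntimeError``) for idiomatic handling.
"""


class VsbrightError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(VsbrightError, ValueError):
    """Malformed input: bad grid, wrong columns, out-of-range parameter."""


class UnitError(ValidationError):
    """An absolute quantity was required but a relative one was passed (or vice versa)."""


class DegenerateSpectrumError(ValidationError):
    """Spectrum carries no usable V-weighted power (integral below tolerance)."""


class DomainError(VsbrightError, ValueError):
    """Model evaluated outside its mathematical domain (e.g. negative base, fractional exponent)."""


class DegenerateFitError(VsbrightError, ValueError):
    """Least-squares problem has no unique solution (zero predictor variance)."""


class UndefinedMetricError(VsbrightError, ValueError):
    """A fit metric is undefined for this input (e.g. zero response variance)."""


class OptimizationError(VsbrightError, RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []
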
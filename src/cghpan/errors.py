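"""Exception types shared across the package."""


class CGHPanError(Exception):
    """Base class for package errors."""


class ConfigError(CGHPanError, ValueError):
    """A simulation configuration violates one of its invariants."""


class ValidationError(CGHPanError, ValueError):
    """An input object violates a precondition of an operation."""


class FittingError(CGHPanError, RuntimeError):
    """Nonlinear fitting failed to converge from any starting point."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss
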
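"""Exception hierarchy shared across the package."""


class NgbKinError(Exception):
    """Base class for all package errors."""


class DomainError(NgbKinError, ValueError):
    """An input violates a physical or mathematical precondition."""


class UnsupportedConfigurationError(NgbKinError):
    """A closed-form solution was requested outside its validity limit."""


class IntegrationError(NgbKinError):
    """The stiff ODE integrator failed; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class FitFailureError(NgbKinError):
    """Nonlinear fit did not converge; carries the best fit so far."""

    def __init__(self, message: str, best_so_far=None):
        super().__init__(message)
        self.best_so_far = best_so_far


class IdentifiabilityError(NgbKinError, ValueError):
    """The data cannot constrain the requested parameters."""


class SegmentationError(NgbKinError):
    """A kinetic trace could not be segmented into phases."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegeneratePartitionError(NgbKinError, ValueError):
    """Both microscopic geminate rates are zero."""


class TraceParseError(NgbKinError, ValueError):
    """A delimited text file could not be parsed; names the bad line."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        super().__init__(message)
        self.path = path
        self.line_number = line_number


class ConfigError(NgbKinError, ValueError):
    """A run-configuration file contains unknown or invalid keys."""
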
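"""Exception hierarchy shared across the package."""


class AzeoblendError(Exception):
    """Base class for all package-specific errors."""


class DomainError(AzeoblendError, ValueError):
    """An argument lies outside its physically meaningful domain."""


class GridMismatchError(AzeoblendError, ValueError):
    """Two spectra were combined without sharing a wavenumber grid."""


class DataIntegrityError(AzeoblendError, ValueError):
    """Input data violate a conservation or monotonicity requirement."""


class FitError(AzeoblendError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics in args."""


class IntegrationError(AzeoblendError, RuntimeError):
    """ODE integration failed; carries the last valid state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class ConfigError(AzeoblendError, ValueError):
    """A configuration file is malformed or out of range."""


class FormatError(AzeoblendError, ValueError):
    """A data file could not be parsed in the declared format."""
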
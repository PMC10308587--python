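"""Exception types shared across the package."""


class OmegaFQError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OmegaFQError):
    """Invalid run configuration or unknown enum value."""


class GeometryError(OmegaFQError):
    """Degenerate or inconsistent nanostructure geometry."""


class ParameterError(OmegaFQError):
    """Unphysical material parameter (e.g. non-positive scattering time)."""


class RangeError(OmegaFQError):
    """Frequency outside a tabulated interval."""


class SolverError(OmegaFQError):
    """Linear solve failed or did not reach the requested residual."""


class ParseError(OmegaFQError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InputError(OmegaFQError):
    """Missing or inconsistent user-supplied data (e.g. a mode without
    displaced tensors)."""
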
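"""Package exception hierarchy."""


class OTFEError(Exception):
    """Base class for package errors."""


class ConfigurationError(OTFEError, ValueError):
    """Invalid potential/protocol specification."""


class ValidationError(OTFEError, ValueError):
    """Invalid data passed to an operation (unnormalized density, bad shape...)."""


class NumericError(OTFEError, RuntimeError):
    """A numerical procedure failed to converge; carries diagnostics in args."""


class SimulationError(OTFEError, RuntimeError):
    """Non-finite energy or force encountered during dynamics."""
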
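"""Exception hierarchy for the toolkit."""


class NeqfeError(Exception):
    """Base class for all toolkit errors."""


class InputError(NeqfeError, ValueError):
    """Malformed numerical input (wrong shape, non-finite values, ...)."""


class ConfigurationError(NeqfeError, ValueError):
    """Inconsistent system / softening / hybrid configuration."""


class IntegrationError(NeqfeError, RuntimeError):
    """Dynamics produced a non-finite energy or force."""


class EstimationError(NeqfeError, RuntimeError):
    """A free-energy estimator could not produce a value."""


class UnsupportedError(NeqfeError, NotImplementedError):
    """Requested operation outside the supported problem sizes."""


class ReservoirError(NeqfeError, RuntimeError):
    """Reservoir generation failed (e.g. every switching run was rejected)."""
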
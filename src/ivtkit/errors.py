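"""Exception types shared across ivtkit."""


class IVTKitError(Exception):
    """Base class for all ivtkit errors."""


class ValidationError(IVTKitError):
    """Invalid user input (negative totals, malformed config, unknown keys)."""


class ConfigurationError(IVTKitError):
    """Inconsistent model configuration (missing omega entry, Ksp <= 0, ...)."""


class SpeciationError(IVTKitError):
    """Equilibrium solver failed to converge; carries residual diagnostics."""

    def __init__(self, message, *, residuals=None, composition=None):
        super().__init__(message)
        self.residuals = residuals
        self.composition = composition


class SimulationError(IVTKitError):
    """Reactor integration failed; carries the last good state."""

    def __init__(self, message, *, time=None, last_state=None):
        super().__init__(message)
        self.time = time
        self.last_state = last_state


class IdentifiabilityError(IVTKitError):
    """Flat likelihood: a parameter direction cannot be identified."""

    def __init__(self, message, *, direction=None):
        super().__init__(message)
        self.direction = direction
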
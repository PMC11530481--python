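"""Exception hierarchy."""


class PBPKEError(Exception):
    """Base class for all package errors."""


class InvalidChemicalError(PBPKEError):
    """A chemical record violates a physical invariant (e.g. mw <= 0)."""


class InvalidGeometryError(PBPKEError):
    """A geometric quantity (donor height, layer thickness, ...) is non-physical."""


class ConfigurationError(PBPKEError):
    """A scenario/parameter configuration cannot be resolved."""


class UnknownComponentError(PBPKEError):
    """A chemical was referenced that is not a component of the vehicle."""


class EmptyVehicleError(PBPKEError):
    """All vehicle component masses are zero; mole fractions are undefined."""


class UndefinedStatisticError(PBPKEError):
    """A statistic (e.g. R^2 with zero variance) is undefined for the input."""


class SolverError(PBPKEError):
    """The ODE integrator failed; carries the last accepted state."""

    def __init__(self, message, last_time=None, last_state=None):
        super().__init__(message)
        self.last_time = last_time
        self.last_state = last_state
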
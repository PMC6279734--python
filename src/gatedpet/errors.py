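"""Exception hierarchy for the gatedpet pipeline."""


class GatedPetError(Exception):
    """Base class for all gatedpet errors."""


class InfeasibleSpecError(GatedPetError):
    """A curve specification cannot be met by the band-limited curve family.

    Carries the name of the violated constraint and the residual achieved.
    """

    def __init__(self, message, constraint=None, residual=None):
        super().__init__(message)
        self.constraint = constraint
        self.residual = residual


class ConvergenceError(GatedPetError):
    """A numerical solver failed to converge; never return a silently wrong curve."""


class DegenerateCurveError(GatedPetError):
    """The volume curve has no usable systole/diastole structure (e.g. constant)."""


class UnreliableGateError(GatedPetError):
    """Too few valid rays to trust the endocardial surface of a gate."""

    def __init__(self, message, gate=None, valid_fraction=None):
        super().__init__(message)
        self.gate = gate
        self.valid_fraction = valid_fraction


class DataError(GatedPetError):
    """Malformed or inconsistent input data (streams, images, configs)."""
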
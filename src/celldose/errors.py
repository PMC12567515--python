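"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class EnergyRangeError(ValueError):
    """Kinetic energy outside the supported 1 keV - 20 MeV window."""


class NoSolutionError(RuntimeError):
    """A root-finding problem has no solution in the searched bracket."""


class FitError(RuntimeError):
    """A model fit failed to converge or the data violate the model."""


class AlignmentError(ValueError):
    """Two time series do not share a common grid."""
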
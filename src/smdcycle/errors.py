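"""Exception hierarchy for smdcycle."""


class SmdCycleError(Exception):
    """Base class for all package errors."""


class InvalidSystemError(SmdCycleError):
    """A toy system violates a structural invariant (empty monomer, bad mass...)."""


class ConfigurationError(SmdCycleError):
    """A restraint set, schedule or run configuration is inconsistent."""


class NumericalBlowupError(SmdCycleError):
    """A non-finite force or coordinate appeared during integration."""


class EstimationError(SmdCycleError):
    """A free-energy estimator received unusable input."""


class AlignmentError(SmdCycleError):
    """Grids or residue sets that must match do not."""


class GeometryError(SmdCycleError):
    """A structural geometry primitive received a degenerate input."""


class ParseError(SmdCycleError):
    """A file could not be parsed."""


class ResolutionError(SmdCycleError):
    """A quadrature did not converge on the supplied grid."""
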
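"""Exception hierarchy for grextrap."""


class GRExtrapError(Exception):
    """Base class for all grextrap errors."""


class ConditioningError(GRExtrapError):
    """A Gram matrix could not be factorized within the jitter budget."""

    def __init__(self, message, offending_pair=None, condition_number=None):
        super().__init__(message)
        self.offending_pair = offending_pair
        self.condition_number = condition_number


class DegenerateSchemeError(GRExtrapError):
    """The denominator determinant of an extrapolation scheme vanishes."""


class DesignInfeasibleError(GRExtrapError):
    """No candidate experiment fits inside the computational budget."""


class GridIncompleteError(GRExtrapError):
    """A multi-output dataset is missing cells of its Cartesian grid."""


class ImproperModeError(GRExtrapError):
    """An operation requiring a proper (finite-k0) prior was requested in the
    improper-limit mode."""
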
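"""Exception hierarchy for the coupling-analysis pipeline.

Every failure mode carries enough context (entity, window, stage) to let a
batch run either abort (strict mode) or exclude the offending unit and log it.
"""


class LVCouplingError(Exception):
    """Base class for all package errors."""


class DomainError(LVCouplingError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class ConfigurationError(LVCouplingError, ValueError):
    """Inconsistent or infeasible configuration (goalposts, weights, grid)."""


class AlignmentError(LVCouplingError, ValueError):
    """Two series that must share (entity, year) keys do not."""


class InsufficientDataError(LVCouplingError, ValueError):
    """Too few observations to carry out the operation."""


class RangeError(LVCouplingError, ValueError):
    """A value falls outside its pooled standardization range."""


class DegenerateInputError(LVCouplingError, ValueError):
    """Structurally degenerate input (e.g. all-zero HDI vector)."""


class UnderdeterminedSystemError(LVCouplingError, ValueError):
    """Fewer increments than coefficients in the least-squares system."""


class SingularFitError(LVCouplingError, ValueError):
    """Design matrix rank-deficient or numerically singular."""


class DegenerateDynamicsError(LVCouplingError, ValueError):
    """Estimated coefficients give non-finite or undefined derived dynamics."""


class UndefinedIndexError(LVCouplingError, ValueError):
    """The mutualism degree index is undefined (both force-on indices zero)."""


class LabelError(LVCouplingError, KeyError):
    """An entity label is unknown or missing a required attribute."""


class GeometryError(LVCouplingError, ValueError):
    """A polygon geometry is invalid or empty."""


class IsolateError(LVCouplingError, ValueError):
    """An entity has no neighbours and no explicit isolate exemption."""


class ConstantValuesError(LVCouplingError, ValueError):
    """Zero variance in the attribute vector: Moran's I undefined."""


class EmptyWeightsError(LVCouplingError, ValueError):
    """All spatial weights are zero."""


class CodingError(LVCouplingError, KeyError):
    """A rank letter has no numeric coding."""


class ParseError(LVCouplingError, ValueError):
    """Malformed input file."""


class DuplicateKeyError(LVCouplingError, ValueError):
    """Duplicate (entity, year, indicator) row in an input panel."""


class SimulationDivergenceError(LVCouplingError, ArithmeticError):
    """The implicit-midpoint recurrence has no real root: dynamics escaped."""
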
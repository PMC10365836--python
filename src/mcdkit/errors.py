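"""Exception hierarchy for mcdkit."""


class MCDError(Exception):
    """Base class for all mcdkit errors."""


class InvalidGeometryError(MCDError):
    """A channel dimension or viscosity is non-positive."""


class UnsolvableNetworkError(MCDError):
    """The network has a component with no boundary pressure."""


class DegenerateNetworkError(MCDError):
    """The nodal pressure system is singular."""


class RecirculationError(MCDError):
    """The flow-directed graph contains a cycle; concentration propagation
    assumes a directed acyclic flow pattern."""


class InfeasibleConstraintsError(MCDError):
    """Design targets violate mass conservation or fixed-edge consistency."""


class InfeasiblePressuresError(MCDError):
    """A designed channel would need a non-positive resistance."""


class InvalidStratificationError(MCDError):
    """Stream width fractions do not sum to one or are non-positive."""


class OutOfDomainError(MCDError):
    """A queried position or time lies outside the evaluated field."""


class DegenerateCalibrationError(MCDError):
    """Low and high calibration references have equal means."""


class NoDataError(MCDError):
    """An operation received an empty mask or empty table."""


class UndefinedIndexError(MCDError):
    """The accumulation-index denominator is zero."""


class ConfigurationError(MCDError):
    """Inconsistent pipeline or panel configuration."""
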
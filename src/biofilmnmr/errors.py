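"""Exception hierarchy shared by all pipeline stages."""


class BiofilmNMRError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(BiofilmNMRError, ValueError):
    """A configuration document violates the schema; the message names the key."""


class InputError(BiofilmNMRError, ValueError):
    """Invalid data handed to an operation (bad mode, empty grid, zero overlap...)."""


class ComputationError(BiofilmNMRError, ArithmeticError):
    """A computation cannot proceed (division by a zero integral, rank-0 matrix...)."""


class FitError(BiofilmNMRError, RuntimeError):
    """A least-squares fit failed to converge or the data are degenerate."""


class DegenerateSystemError(ComputationError):
    """The proportion system is singular: the two component ratios coincide."""


class InconsistentProportionsError(ComputationError):
    """The proportion solution leaves [0, 100]%, violating the equal-volume,
    equal-biomass assumptions of the degradation model; raw values are reported
    instead of being silently clamped."""
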
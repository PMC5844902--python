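"""Exception hierarchy.

The CLI maps these onto exit codes: configuration errors -> 2, numerical
failures -> 3, corrupt archives -> 4.
"""


class SwitchPathError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SwitchPathError):
    """Invalid user input, construct definition or run configuration."""


class MissingChainError(ConfigurationError):
    """Requested chain absent from the structure."""


class ChainGapError(ConfigurationError):
    """Residues without a Cα atom in the requested chain."""


class ConstructionError(ConfigurationError):
    """AFF construct assembly produced an inconsistent topology."""


class NumericalError(SwitchPathError):
    """Numerical failure during simulation or analysis."""


class NonFiniteEnergyError(NumericalError):
    """Potential energy evaluated to a non-finite value (bead overlap)."""


class TimestepError(NumericalError):
    """Per-step displacement exceeded the integrator sanity bound."""


class CalibrationError(NumericalError):
    """Contact-strength calibration could not bracket or reach the target."""


class UndefinedSuperpositionError(NumericalError):
    """RMSD superposition requested on fewer than three points."""


class UndefinedStateError(SwitchPathError):
    """State definitions could not be derived (e.g. unimodal histogram)."""


class CorruptArchiveError(SwitchPathError):
    """A WE iteration archive is internally inconsistent."""
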
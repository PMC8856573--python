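"""Exception hierarchy for dwisynth."""


class DwisynthError(Exception):
    """Base class for all dwisynth errors."""


class InputFileError(DwisynthError):
    """An input file is missing or cannot be parsed as NIfTI."""


class GridMismatchError(DwisynthError):
    """Two images that must share a voxel grid do not."""


class ConvergenceError(DwisynthError):
    """The stepwise Bloch propagation did not reach steady state."""


class ConditioningError(DwisynthError):
    """The tissue-signal design matrix is numerically singular."""


class ConfigError(DwisynthError):
    """A configuration file is malformed or contains unknown keys."""
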
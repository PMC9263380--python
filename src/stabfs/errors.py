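"""Exception hierarchy shared across the package."""


class StabfsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StabfsError, ValueError):
    """An invalid configuration value; the message names the violated invariant."""


class ParameterError(StabfsError, ValueError):
    """An operation parameter out of its admissible range."""


class DataError(StabfsError, ValueError):
    """Malformed or inconsistent input data (missing values, id mismatches, ...)."""


class SplitError(StabfsError, ValueError):
    """A train/test split that cannot satisfy the stratification contract."""


class DegenerateStabilityError(StabfsError, ValueError):
    """Stability undefined: every feature always selected, or never selected."""


class GraphStructureError(StabfsError, ValueError):
    """An affinity graph unusable for spectral scoring (e.g. empty)."""
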
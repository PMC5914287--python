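"""Exception hierarchy for pipeline stages.

Exit-code mapping used by the CLI: ConfigError -> 2, DataInconsistencyError -> 3.
"""


class DasypopError(Exception):
    """Base class for all package errors."""


class ConfigError(DasypopError):
    """Invalid configuration (bad thresholds, unfittable urban discs, missing files)."""


class AlignmentError(DasypopError):
    """Two rasters do not share the same grid specification."""


class DataInconsistencyError(DasypopError):
    """Census tables disagree (e.g. urban population exceeds county total)."""


class FitError(DasypopError):
    """A regression cannot be fitted (too few points, zero variance)."""


class AllocationError(DasypopError):
    """A zone cannot receive its population (empty zone with people to place)."""
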
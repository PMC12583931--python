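"""Typed errors raised by pipeline stages."""


class ScgPipeError(Exception):
    """Base class for all scgpipe errors."""


class InvalidConfigError(ScgPipeError, ValueError):
    """A configuration value violates its constraints."""


class SessionRejectedError(ScgPipeError):
    """A recording session has no usable data left after exclusion."""


class SessionUnusableError(ScgPipeError):
    """R-peak detection could not find enough beats to proceed."""


class DegenerateBeatError(ScgPipeError):
    """A beat is flat (zero peak-to-peak amplitude) and cannot be normalized."""


class DegenerateSplitError(ScgPipeError):
    """The respiration covariate is constant; a median split is undefined."""


class ClusteringFailedError(ScgPipeError):
    """All candidate initializations produced degenerate clusterings."""


class FeatureUnavailableError(ScgPipeError):
    """A feature is undefined on this input (e.g. too few beats, zero matches)."""


class MissingDependencyError(ScgPipeError):
    """A pipeline stage requires the output of a stage that was not run."""
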
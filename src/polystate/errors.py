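"""Exceptions and warnings shared across the package."""


class PolystateError(Exception):
    """Base class for all package-specific errors."""


class TrackParseError(PolystateError):
    """A track file line could not be parsed; carries the 1-based line number."""

    def __init__(self, path, line_number, message):
        self.path = str(path)
        self.line_number = line_number
        super().__init__(f"{path}:{line_number}: {message}")


class DuplicateProbeError(PolystateError):
    """Two probes at the same genomic position on one chromosome."""


class ValidationError(PolystateError):
    """An object violates a structural invariant (coordinates, signs, shapes)."""


class AnnotationError(PolystateError):
    """A gene annotation record is malformed (missing strand, empty span...)."""


class NoSharedProbesError(PolystateError):
    """Two tracks have no probe positions in common."""


class UndefinedCorrelationError(PolystateError):
    """Correlation requested on <2 shared probes or a zero-variance vector."""


class DegenerateNullError(PolystateError):
    """The delta null distribution has zero spread; thresholds are undefined."""


class UnusablePairError(PolystateError):
    """A 3C primer pair has no usable control quantity (BAC control is zero)."""


class FragmentMapError(PolystateError):
    """3C fragments could not be mapped to genomic coordinates."""

    def __init__(self, fragment_ids):
        self.fragment_ids = list(fragment_ids)
        super().__init__(f"unmapped fragments: {', '.join(map(str, self.fragment_ids))}")


class ProfileMismatchError(PolystateError):
    """Two interaction profiles do not share the same anchor/fragment set."""


class SimulationError(PolystateError):
    """A synthetic-data configuration is infeasible or inconsistent."""


class ConfigError(PolystateError):
    """A pipeline configuration is invalid or references missing inputs."""


class StageError(PolystateError):
    """A pipeline stage failed; names the stage and wraps the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


class EmptyIntersectionWarning(UserWarning):
    """Two tracks share no probes; downstream vectors are empty."""


class NullShiftWarning(UserWarning):
    """The delta null median is far from zero relative to its spread."""
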
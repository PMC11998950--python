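"""Exception and warning types shared across the package."""


class TubeHctError(Exception):
    """Base class for all package errors."""


class InvalidPoseError(TubeHctError):
    """Camera pose has non-finite angles or impossible geometry."""


class ProjectionError(TubeHctError):
    """A world point lies at or behind the camera plane."""


class FramingError(TubeHctError):
    """The tube does not fit inside the camera field of view."""


class ConfigError(TubeHctError):
    """Invalid configuration value (palette, range, occupancy, ...)."""


class DegenerateSampleError(TubeHctError):
    """Marker geometry implies a zero-length sample column."""


class MarkerOrderError(TubeHctError):
    """Buffy marker lies outside the [upper, lower] interval."""


class StateError(TubeHctError):
    """Operation not allowed in the current adjustment state."""


class NoTubeError(TubeHctError):
    """No tube-like region found in the image."""


class OrientationError(TubeHctError):
    """Tube axis is tilted beyond the supported range; rotate first."""


class ClassificationError(TubeHctError):
    """Too many image rows could not be assigned a zone label."""


class DetectionError(TubeHctError):
    """Zone sequence is inconsistent with a centrifuged tube."""


class DesignError(TubeHctError):
    """Trial table is not a complete/balanced design for the statistic."""


class DegenerateDataError(TubeHctError):
    """Statistic undefined because the data carry no variance."""


class InsufficientDataError(TubeHctError):
    """Too few observations for the requested statistic."""


class ConflictError(TubeHctError):
    """A record with this sample id already exists in the store."""


class EmptyStoreError(TubeHctError):
    """The record store contains no records to export."""


class IntegrityWarning(UserWarning):
    """Stored Hct disagrees with the Hct recomputed from the markers."""
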
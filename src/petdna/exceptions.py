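"""Exception hierarchy shared across the package."""


class PetdnaError(Exception):
    """Base class for all package errors."""


class VolumeIOError(PetdnaError):
    """A volume file could not be read or written."""


class AlignmentError(PetdnaError):
    """SUV volume and mask do not live on the same voxel grid."""


class ValidationError(PetdnaError):
    """An input value violates its contract (range, sign, shape)."""


class UndefinedFeatureError(PetdnaError):
    """A feature is requested on an empty lesion set (patient must be excluded upstream)."""


class StageError(PetdnaError):
    """A pipeline stage failed; the message names the stage."""
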
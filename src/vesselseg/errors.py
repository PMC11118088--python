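"""Exception types shared across the package."""


class VesselSegError(Exception):
    """Base class for package errors."""


class DimensionError(VesselSegError, ValueError):
    """A tensor/image has an incompatible shape; the message names the axis."""


class ConfigurationError(VesselSegError, ValueError):
    """An invalid architecture or training configuration, detected at build time."""


class DatasetError(VesselSegError, IOError):
    """A dataset directory or file could not be read as documented."""


class CheckpointError(VesselSegError, ValueError):
    """A checkpoint does not match the model/config it is loaded into."""
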
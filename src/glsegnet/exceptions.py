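"""Package exceptions."""


class GLSegnetError(Exception):
    """Base class for package errors."""


class ConfigurationError(GLSegnetError):
    """A module was configured inconsistently (channel/shape/hyperparameters)."""


class ShapeError(GLSegnetError):
    """Runtime arrays do not satisfy a shape contract."""


class GenerationError(GLSegnetError):
    """A synthetic sample could not be generated under the given spec."""


class DataError(GLSegnetError):
    """A dataset directory violates the images/masks contract."""
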
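"""Exception hierarchy."""


class SffAlignError(Exception):
    """Base class for all package errors."""


class ModelError(SffAlignError):
    """The pair HMM is malformed or unusable for the requested operation."""


class ParameterError(SffAlignError):
    """A model-building parameter is out of range."""


class InputError(SffAlignError):
    """A sequence or other user input is invalid."""


class FormatError(SffAlignError):
    """A file could not be parsed."""


class ZeroProbabilityError(SffAlignError):
    """The model assigns probability zero to the observed sequence pair."""


class ConfigurationError(SffAlignError):
    """A run configuration is inconsistent or a sampling constraint failed."""
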
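"""Exception hierarchy shared across the pipeline stages."""


class PoolfitError(Exception):
    """Base class for all package-specific failures."""


class FormatError(PoolfitError):
    """A file does not conform to the expected dialect."""


class ConsistencyError(PoolfitError):
    """Two inputs that must agree (e.g. matrix rows vs strain key) do not."""


class NormalizationError(PoolfitError):
    """Normalization cannot proceed (e.g. no usable spots on an array)."""


class StandardizationError(PoolfitError):
    """Z-standardization is undefined (constant or near-empty input)."""
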
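"""Exception hierarchy for shadowcell."""


class ShadowCellError(Exception):
    """Base class for all shadowcell errors."""


class FormatError(ShadowCellError):
    """Unsupported or malformed image/file format."""


class ConfigurationError(ShadowCellError):
    """Invalid configuration or mismatched shapes/parameters."""


class BoundsError(ShadowCellError):
    """A coordinate lies outside the image."""


class UndefinedMetricError(ShadowCellError):
    """A metric is undefined for the given inputs (zero denominator, n too small)."""


class CapacityError(ShadowCellError):
    """The requested object density cannot be placed in the scene."""
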
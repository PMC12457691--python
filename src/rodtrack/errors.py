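"""Exception types shared across the package."""


class ConfigError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class InsufficientDataError(ValueError):
    """Too few observations for the requested estimate."""


class ShapeExtractionError(ValueError):
    """A cell contour that does not admit a medial-axis decomposition."""
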
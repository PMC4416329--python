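"""Exception hierarchy for glyvar."""


class GlyvarError(Exception):
    """Base class for all glyvar errors."""


class InputFormatError(GlyvarError):
    """A CGM export could not be parsed (missing column, bad timestamp, ...)."""


class GridError(GlyvarError):
    """Grid alignment or windowing failed (slot collision, empty window, ...)."""


class ConfigError(GlyvarError):
    """An analysis configuration value is invalid."""
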
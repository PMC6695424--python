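"""Exception hierarchy.

All package-specific errors derive from :class:`TwitchIndexError` so callers
can catch one base class at pipeline boundaries.
"""


class TwitchIndexError(Exception):
    """Base class for all twitchindex errors."""


class ParameterError(TwitchIndexError, ValueError):
    """A user-supplied parameter violates a precondition."""


class GeometryError(TwitchIndexError, RuntimeError):
    """Synthetic geometry could not be realised (e.g. nuclei placement failed)."""


class FormatError(TwitchIndexError, ValueError):
    """An input file does not have the expected structure."""


class SchemaError(TwitchIndexError, ValueError):
    """A table is missing required columns, rows or conditions."""


class NoContractionDetected(TwitchIndexError):
    """No activity peak exceeded the prominence floor; the field looks static."""


class InsufficientFrames(TwitchIndexError):
    """Not a single complete contraction/relaxation pair fits in the stack."""
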
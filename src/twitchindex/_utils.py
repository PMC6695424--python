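"""Small shared helpers."""

import math

from .errors import ParameterError


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-ward ties upward.

    Frame-index arithmetic uses this convention throughout (Python's builtin
    ``round`` is banker's rounding, which would map 28.5 to 28).
    """
    return int(math.floor(x + 0.5))


def require(condition: bool, message: str, exc: type = ParameterError) -> None:
    if not condition:
        raise exc(message)
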
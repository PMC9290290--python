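"""Small shared helpers."""
from __future__ import annotations

import math


class ValidationError(ValueError):
    """Raised when an input table or argument violates a documented contract."""


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message carries the stage name."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (0.005 -> 0.01), as printed tables do."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def percent(part: float, whole: float, ndigits: int = 2) -> float:
    """100 * part / whole, rounded half-up to ``ndigits`` decimals."""
    if whole == 0:
        raise ValidationError("percentage denominator is zero")
    return round_half_up(100.0 * part / whole, ndigits)
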
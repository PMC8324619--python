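"""Small shared helpers: reporting-style rounding and package exceptions."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


class ConfigurationError(RuntimeError):
    """A geometric or protocol configuration cannot be realized."""


class UnitsError(ValueError):
    """An operation was applied to a volume in the wrong units."""


class OutOfBoundsError(ValueError):
    """A requested object does not fit inside the voxel grid."""


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves going away from zero (reporting convention).

    Python's built-in ``round`` uses banker's rounding, which would turn a
    mean sensitivity of 72.25 into 72.2; clinical reports round it to 72.3.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
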
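"""Display rounding used throughout the package.

Stored values are never rounded; these helpers exist only for reproducing
published display precision (round-half-up, the convention of the source
tables) and for the ceiling rules used by the person-count quantities.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "ceil_guarded"]

# Binary floats carry ~1e-16 relative noise; a value that is mathematically
# half-way at the display precision (e.g. 40.815 at 2 decimals) may sit a hair
# on either side.  Snap at 4 guard digits (half-even) before the half-up step.
_GUARD = 4


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round ``x`` half-up at ``ndigits`` decimal places."""
    d = Decimal(repr(float(x)))
    d = d.quantize(Decimal(1).scaleb(-(ndigits + _GUARD)), rounding=ROUND_HALF_EVEN)
    return float(d.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def ceil_guarded(x: float) -> int:
    """Ceiling of ``x``, immune to float noise just above an integer.

    ``ceil(56.000000000000007)`` must be 56, not 57, when the exact value
    is 56; noise below 1e-9 is absorbed.
    """
    return math.ceil(round(x, 9))
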
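"""Small shared helpers."""

from __future__ import annotations

import math


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (the convention of clinical tables).

    Python's built-in ``round`` uses banker's rounding; reported percentages
    in the tables this package mirrors round 0.5 up in magnitude instead.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
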
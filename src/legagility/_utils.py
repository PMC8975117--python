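"""Small shared helpers."""

from __future__ import annotations

import numpy as np


def round_half_away(x):
    """Round half away from zero (2.5 -> 3, -2.5 -> -3).

    Python's built-in ``round`` is banker's rounding; clinical score labels
    use the convention that a mean of 2.5 becomes a 3.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    if out.ndim == 0:
        return float(out)
    return out
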
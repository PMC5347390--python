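"""Small numerical helpers shared across models."""

from __future__ import annotations

import numpy as np

__all__ = ["complement_power", "safe_ratio"]


def complement_power(p: float, n: float) -> float:
    """Evaluate 1 - (1 - p)**n without underflow for tiny p.

    Computed as -expm1(n * log1p(-p)), which keeps full relative precision
    down to p ~ 1e-300 and for n as large as 2**63.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability out of range: {p!r}")
    if p == 1.0:
        return 1.0
    return float(-np.expm1(n * np.log1p(-p)))


def safe_ratio(num: float, den: float) -> float:
    """num / den, with NaN (the tables' "NA") when the denominator is zero."""
    if den == 0.0:
        return float("nan")
    return num / den
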
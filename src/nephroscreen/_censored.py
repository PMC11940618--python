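"""Right-censored concentration values.

A point of departure that is not reached within the tested concentration
range is reported as a strict lower bound ("> 300 µM") rather than a point
estimate; the same bookkeeping propagates through free-concentration
adjustment and margin-of-safety ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CensoredValue:
    """A concentration (or ratio) that may be a strict lower bound.

    Parameters
    ----------
    value : float
        The point estimate, or — when ``censored`` is True — the bound b in
        "> b".
    censored : bool
        True when the quantity exceeds ``value`` but its magnitude is unknown.
    """

    value: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")
        if self.value < 0:
            raise ValueError(f"value must be non-negative, got {self.value}")

    def scaled(self, factor: float) -> "CensoredValue":
        """Multiply by a positive factor; a censored bound scales with it."""
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        return CensoredValue(self.value * factor, self.censored)

    def __str__(self) -> str:
        return f"> {self.value:g}" if self.censored else f"{self.value:g}"


def as_censored(x: "float | CensoredValue") -> CensoredValue:
    """Coerce a plain number to an uncensored :class:`CensoredValue`."""
    if isinstance(x, CensoredValue):
        return x
    return CensoredValue(float(x), censored=False)
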
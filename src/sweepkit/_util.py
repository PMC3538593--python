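"""Small numerical helpers shared across modules."""

from __future__ import annotations

import numpy as np


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's denominator for sample size n)."""
    if n < 2:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n)))


def harmonic2(n: int) -> float:
    """b_n = sum_{i=1}^{n-1} 1/i^2."""
    if n < 2:
        return 0.0
    return float(np.sum(1.0 / np.arange(1, n) ** 2))


class UndefinedStatistic:
    """Sentinel for statistics that are undefined on the given input.

    Truthy-falsy as False, prints as "n. a.". Carries a reason so reports can
    explain why a cell is empty.
    """

    __slots__ = ("reason",)

    def __init__(self, reason: str = ""):
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"UndefinedStatistic({self.reason!r})"

    def __str__(self) -> str:
        return "n. a."

    def __bool__(self) -> bool:
        return False

    def __eq__(self, other) -> bool:
        return isinstance(other, UndefinedStatistic)

    def __hash__(self):
        return hash("UndefinedStatistic")


UNDEFINED = UndefinedStatistic()


def is_undefined(x) -> bool:
    return isinstance(x, UndefinedStatistic)
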
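"""Numeric formatting for human-readable report tables.

Conventions: diversity/divergence to 3 decimals, test statistics to 2,
p-values to 3 with a "<1/reps" bound when no replicate was as extreme,
"n. a." for undefined cells.
"""

from __future__ import annotations

from sweepkit._util import is_undefined
from sweepkit.coalsim import PValue

NA = "n. a."


def fmt(x, nd: int = 3) -> str:
    if x is None or is_undefined(x):
        return NA
    try:
        xf = float(x)
    except (TypeError, ValueError):
        return str(x)
    if xf != xf:  # nan
        return NA
    return f"{xf:.{nd}f}"


def fmt_stat(x) -> str:
    return fmt(x, 2)


def fmt_pvalue(p) -> str:
    if p is None or is_undefined(p):
        return NA
    if isinstance(p, PValue):
        return str(p)
    return fmt(p, 3)


def fmt_count(x) -> str:
    if x is None or is_undefined(x):
        return NA
    xf = float(x)
    if xf == int(xf):
        return str(int(xf))
    return f"{xf:.1f}"


def fmt_s_with_singletons(s, singletons) -> str:
    if s is None:
        return NA
    return f"{int(s)} ({int(singletons)})"
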
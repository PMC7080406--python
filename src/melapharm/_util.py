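"""Shared helpers: censored values and reporting-grade rounding."""
from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class Bound:
    """A censored measurement: a one-sided bound, never a plain number.

    ``op`` is ``'>'`` or ``'<'``; ``value`` is on the same scale as the
    uncensored quantity. ``Bound('>', 30000)`` renders as ``">30000"``.
    """

    op: str
    value: float

    def __post_init__(self) -> None:
        if self.op not in (">", "<"):
            raise ValueError(f"bound op must be '>' or '<', got {self.op!r}")

    def __str__(self) -> str:
        return f"{self.op}{self.value:g}"


def parse_reported(text) -> float | Bound | None:
    """Parse a printed table cell: a number, 'ND' (-> None) or '>X'/'<X'."""
    if text is None:
        return None
    if isinstance(text, (int, float)):
        return None if (isinstance(text, float) and math.isnan(text)) else float(text)
    s = str(text).strip()
    if s in ("", "ND", "nd", "NA", "nan"):
        return None
    if s[0] in "<>":
        return Bound(s[0], float(s[1:]))
    return float(s)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (the convention of printed tables),
    rather than banker's rounding."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
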
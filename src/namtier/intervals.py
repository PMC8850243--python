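"""Closed dose intervals and display-rounding helpers.

All internal doses are in mg/kg bw/day unless a record explicitly carries
another unit (percent for dermal sensitisation, µM for pre-IVIVE in vitro
points of departure). A point value is an interval with ``lo == hi``.
No rounding happens at computation level; :func:`format_sig` is the report
layer's significant-figure formatter.
"""

from __future__ import annotations

import math
from typing import Any

from pydantic import BaseModel, ConfigDict, model_validator


class DoseInterval(BaseModel):
    """Closed interval ``[lo, hi]`` of non-negative doses."""

    model_config = ConfigDict(frozen=True)

    lo: float
    hi: float

    @model_validator(mode="before")
    @classmethod
    def _coerce(cls, data: Any) -> Any:
        if isinstance(data, (int, float)):
            return {"lo": float(data), "hi": float(data)}
        if isinstance(data, (list, tuple)):
            if len(data) != 2:
                raise ValueError("an interval is [lo, hi]")
            return {"lo": float(data[0]), "hi": float(data[1])}
        return data

    @model_validator(mode="after")
    def _check(self) -> "DoseInterval":
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError("dose bounds must be finite")
        if self.lo < 0:
            raise ValueError("doses cannot be negative")
        if self.lo > self.hi:
            raise ValueError(f"interval lower bound {self.lo} exceeds upper bound {self.hi}")
        return self

    @classmethod
    def point(cls, value: float) -> "DoseInterval":
        return cls(lo=value, hi=value)

    @property
    def is_point(self) -> bool:
        return self.lo == self.hi

    def scale(self, k: float) -> "DoseInterval":
        if k < 0:
            raise ValueError("scale factor must be non-negative")
        return DoseInterval(lo=self.lo * k, hi=self.hi * k)

    def __truediv__(self, k: float) -> "DoseInterval":
        if k <= 0:
            raise ValueError("divisor must be positive")
        return self.scale(1.0 / k)

    def __str__(self) -> str:  # pragma: no cover - convenience
        if self.is_point:
            return f"{self.lo:g}"
        return f"{self.lo:g}-{self.hi:g}"


def format_sig(value: float, sig: int = 2) -> str:
    """Round ``value`` to ``sig`` significant figures for display."""
    if value == 0:
        return "0"
    if sig < 1:
        raise ValueError("need at least one significant figure")
    text = f"{value:.{sig}g}"
    # avoid exponent notation for the dose magnitudes reports deal in
    if "e" in text or "E" in text:
        x = float(text)
        decimals = max(0, sig - 1 - math.floor(math.log10(abs(x))))
        text = f"{x:.{decimals}f}"
    return text


def format_interval(interval: DoseInterval, sig: int = 2) -> str:
    if interval.is_point:
        return format_sig(interval.lo, sig)
    return f"{format_sig(interval.lo, sig)}–{format_sig(interval.hi, sig)}"
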
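"""Shared domain types and unit conventions for the screening protocols.

Visual acuity is handled in two interchangeable notations:

* a Snellen fraction 20/``denominator`` (the testing-distance convention of
  US clinical charts), and
* logMAR, the base-10 logarithm of the minimum angle of resolution, with
  20/20 at 0.0 and 20/200 at 1.0 (lower is better).

Acuities worse than the largest optotype the protocol can present (20/400)
are not representable as a number; they carry an explicit "below floor"
flag and any statistic that needs a numeric value must exclude or cap them.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "ProtocolStateError",
    "Eye",
    "VisualAcuity",
    "ChartLadder",
    "DEFAULT_LADDER",
    "SNELLEN_FLOOR",
    "snellen_to_logmar",
    "logmar_to_snellen",
    "round_half_away",
    "round_percent",
]

#: Largest presentable optotype; "worse than 20/400" is the protocol floor.
SNELLEN_FLOOR = 400


class ProtocolStateError(RuntimeError):
    """An operation was applied to a protocol state it is not valid in
    (e.g. stepping a finished staircase or an ended acuity run)."""


class Eye(str, enum.Enum):
    """Ocular laterality in the clinical OD/OS convention."""

    OD = "OD"  # oculus dexter, right eye
    OS = "OS"  # oculus sinister, left eye

    @property
    def fellow(self) -> "Eye":
        """The other eye."""
        return Eye.OS if self is Eye.OD else Eye.OD


def snellen_to_logmar(denominator: float) -> float:
    """Convert a Snellen fraction 20/``denominator`` to logMAR.

    Parameters
    ----------
    denominator
        The Snellen denominator (e.g. 40 for 20/40). Must be positive.

    Returns
    -------
    float
        ``log10(denominator / 20)``; 0.0 for 20/20, 1.0 for 20/200.
    """
    if denominator <= 0:
        raise ValueError(f"Snellen denominator must be positive, got {denominator!r}")
    return math.log10(denominator / 20.0)


def logmar_to_snellen(logmar: float, ladder: "ChartLadder | None" = None) -> float:
    """Convert logMAR back to a Snellen denominator.

    With ``ladder`` given, the result is snapped to the nearest chart line
    (nearest in logMAR), which makes the conversion the exact inverse of
    :func:`snellen_to_logmar` for any on-chart acuity.
    """
    raw = 20.0 * 10.0 ** logmar
    if ladder is None:
        return raw
    return min(ladder.sizes, key=lambda s: abs(snellen_to_logmar(s) - logmar))


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of clinical reporting),
    unlike banker's rounding used by builtin :func:`round`."""
    factor = 10.0 ** decimals
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5)
    return math.copysign(rounded, scaled) / factor


def round_percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half away from zero.

    This is the single reporting convention used for every rate in the
    package (sensitivity, specificity, prevalence, percent improvement), so
    printed values match clinical-report arithmetic: 1/121 -> 0.83 at two
    decimals, 2/204 -> 1 at zero decimals.
    """
    if denominator == 0:
        raise ValueError("round_percent: zero denominator")
    if decimals < 0:
        raise ValueError("round_percent: decimals must be >= 0")
    return round_half_away(100.0 * numerator / denominator, decimals)


@dataclass(frozen=True, order=False)
class VisualAcuity:
    """A visual acuity as a Snellen fraction 20/``snellen_denominator``.

    ``below_floor`` marks acuities recorded as "worse than 20/400": the
    denominator is pinned at the floor value and the record compares as
    strictly worse than every numeric acuity.
    """

    snellen_denominator: float
    below_floor: bool = False

    def __post_init__(self) -> None:
        if self.snellen_denominator <= 0:
            raise ValueError("Snellen denominator must be positive")
        if self.below_floor and self.snellen_denominator != SNELLEN_FLOOR:
            raise ValueError(
                "below-floor acuity must carry the floor denominator "
                f"{SNELLEN_FLOOR}, got {self.snellen_denominator}"
            )

    @classmethod
    def worse_than_floor(cls) -> "VisualAcuity":
        """The 'less than 20/400' record."""
        return cls(SNELLEN_FLOOR, below_floor=True)

    @property
    def logmar(self) -> float:
        """logMAR value; raises for below-floor records, which have none."""
        if self.below_floor:
            raise ValueError("acuity below floor has no numeric logMAR value")
        return snellen_to_logmar(self.snellen_denominator)

    def is_worse_than_or_equal(self, denominator: float) -> bool:
        """True when this acuity is 20/``denominator`` or worse."""
        return self.below_floor or self.snellen_denominator >= denominator

    def is_worse_than(self, denominator: float) -> bool:
        """True when this acuity is strictly worse than 20/``denominator``."""
        return self.below_floor or self.snellen_denominator > denominator

    def __str__(self) -> str:
        if self.below_floor:
            return f"<20/{SNELLEN_FLOOR}"
        d = self.snellen_denominator
        return f"20/{int(d) if float(d).is_integer() else d}"


#: Standard Snellen chart progression from the 20/400 ceiling line to 20/20.
DEFAULT_SIZES = (400, 200, 100, 80, 60, 50, 40, 30, 25, 20)

#: Lines the protocol references by name and therefore requires on any ladder.
_REQUIRED_SIZES = frozenset({400, 60, 30, 25, 20})


@dataclass(frozen=True)
class ChartLadder:
    """The ordered set of optotype sizes a session presents, largest first."""

    sizes: tuple = DEFAULT_SIZES

    def __post_init__(self) -> None:
        sizes = tuple(self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("chart ladder sizes must be strictly decreasing")
        missing = _REQUIRED_SIZES - set(sizes)
        if missing:
            raise ValueError(f"chart ladder missing protocol lines: {sorted(missing)}")

    @property
    def largest(self) -> float:
        return self.sizes[0]

    @property
    def smallest(self) -> float:
        return self.sizes[-1]

    def __contains__(self, size: float) -> bool:
        return size in self.sizes

    def __iter__(self) -> Iterator[float]:
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    def next_smaller(self, size: float) -> float | None:
        """The next (smaller) line after ``size``, or None at the bottom."""
        i = self.sizes.index(size)
        return self.sizes[i + 1] if i + 1 < len(self.sizes) else None


DEFAULT_LADDER = ChartLadder()
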
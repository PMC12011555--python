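"""Hibernation energy budget from capture-mark-recapture body masses.

A fat-storing hibernator spends the whole hibernation window on reserves
accumulated before entry. Given the mean pre-hibernation (September) and
post-emergence (May) body masses, the budget is simple arithmetic:

    total loss      = BM_entry - BM_exit                 [g]
    daily loss      = total loss / window duration        [g/day]
    relative loss   = 100 * daily loss / BM_entry         [%/day]

A pre-hibernation deficit of ``d`` grams depletes the same reserves
``d / daily loss`` days earlier, shifting the projected emergence date
forward from the window end.

Conventions: the window is fixed at 1 October - 30 April counted
inclusively with February always taken as 28 days (212 days for the full
window, leap years deliberately ignored); rates are reported half-up at
two decimals, with the relative rate computed from the rounded daily rate;
day shifts round to the nearest whole day.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

__all__ = [
    "EnergyBudget",
    "EnergyBudgetError",
    "hibernation_duration",
    "daily_loss",
    "depletion_shift",
    "projected_emergence",
    "DEFAULT_WINDOW",
]


class EnergyBudgetError(ValueError):
    """Invalid window or mass inputs for the energy budget."""


#: Canonical hibernation window of the non-leap wrap year used for projections.
DEFAULT_WINDOW = (dt.date(2018, 10, 1), dt.date(2019, 4, 30))


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10.0**ndigits
    return math.floor(x * scale + 0.5) / scale


def _leap_days_between(start: dt.date, end: dt.date) -> int:
    count = 0
    for year in range(start.year, end.year + 1):
        try:
            feb29 = dt.date(year, 2, 29)
        except ValueError:
            continue
        if start <= feb29 <= end:
            count += 1
    return count


def hibernation_duration(start: dt.date, end: dt.date) -> int:
    """Length of the hibernation window in days.

    Inclusive day count with February always counted as 28 days, so the
    default 1 October - 30 April window is 212 days regardless of leap
    years.
    """
    if end <= start:
        raise EnergyBudgetError(f"window end {end} not after start {start}")
    return (end - start).days + 1 - _leap_days_between(start, end)


@dataclass(frozen=True)
class EnergyBudget:
    """Mass-loss budget over one hibernation window."""

    bm_entry: float
    bm_exit: float
    window: tuple[dt.date, dt.date]
    duration: int

    @property
    def total_loss(self) -> float:
        return self.bm_entry - self.bm_exit

    @property
    def daily_loss_exact(self) -> float:
        """Unrounded loss rate in g/day (drives the depletion projection)."""
        return self.total_loss / self.duration

    @property
    def daily_loss(self) -> float:
        """Loss rate in g/day, half-up at 2 decimals."""
        return _round_half_up(self.daily_loss_exact, 2)

    @property
    def relative_daily_loss(self) -> float:
        """Loss rate as % of entry mass per day, from the rounded daily rate."""
        return _round_half_up(100.0 * self.daily_loss / self.bm_entry, 2)


def daily_loss(
    bm_entry: float,
    bm_exit: float,
    duration: int,
    window: tuple[dt.date, dt.date] = DEFAULT_WINDOW,
) -> EnergyBudget:
    """Build the energy budget from entry/exit masses and a window length."""
    if duration <= 0:
        raise EnergyBudgetError("duration must be positive")
    if not (bm_entry > bm_exit > 0):
        raise EnergyBudgetError(
            f"need bm_entry > bm_exit > 0, got {bm_entry} g and {bm_exit} g "
            "(mass gain over hibernation is out of model scope)"
        )
    return EnergyBudget(
        bm_entry=float(bm_entry),
        bm_exit=float(bm_exit),
        window=window,
        duration=int(duration),
    )


def depletion_shift(deficit: float, budget: EnergyBudget) -> int:
    """Days earlier the reserves run out for a given entry-mass deficit (g)."""
    if deficit < 0:
        raise EnergyBudgetError("deficit must be non-negative")
    rate = budget.daily_loss_exact
    if rate <= 0:
        raise EnergyBudgetError("degenerate budget: zero daily loss")
    return int(_round_half_up(deficit / rate))


def projected_emergence(
    window_end: dt.date, shift: int, window_start: dt.date | None = None
) -> dt.date:
    """Projected emergence date: the window end moved ``shift`` days earlier."""
    if shift < 0:
        raise EnergyBudgetError("shift must be non-negative")
    if window_start is not None:
        length = hibernation_duration(window_start, window_end)
        if shift > length:
            raise EnergyBudgetError(
                f"shift of {shift} days exceeds the {length}-day window"
            )
    return window_end - dt.timedelta(days=int(shift))
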
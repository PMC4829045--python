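"""Seasonal timing of LAG deposition inferred from oxytetracycline marks.

An OTC injection time-stamps the bone: the fluorescent mark records the
humerus diameter on the (known) injection date.  Back-calculating SCL
from the OTC-mark diameter and from the calendar-matched LAG diameter
and comparing the two tells whether that year's LAG was deposited
before, after, or at approximately the same time as the injection.
Aggregating those relations over turtles injected at different times of
year brackets the deposition season.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum

from .backcalc import back_calculate_length
from .core import BackCalcParams, BoneProfile, TurtleRecord
from .errors import DataAvailabilityError, DegenerateSampleError, ParameterError

__all__ = [
    "Relation",
    "TimingClassification",
    "DepositionWindow",
    "classify_deposition",
    "infer_deposition_window",
    "otc_fallback_length",
]

#: SCLs within this of each other are indistinguishable at the 0.1 cm
#: measurement/reporting resolution of carapace lengths.
DEFAULT_COINCIDENCE_TOLERANCE_CM = 0.1


class Relation(str, Enum):
    LAG_BEFORE_INJECTION = "lag_before_injection"
    COINCIDENT = "coincident"
    LAG_AFTER_INJECTION = "lag_after_injection"


@dataclass(frozen=True)
class TimingClassification:
    turtle_id: str
    injection_date: dt.date
    scl_from_otc: float  # cm, back-calculated from the OTC-mark diameter
    scl_from_lag: float  # cm, back-calculated from the calendar-matched LAG
    relation: Relation
    lag_year: int | None = None


@dataclass(frozen=True)
class DepositionWindow:
    """Seasonal (month/day) bracket on when annual LAGs are deposited.

    ``lower_bound`` comes from injections that *preceded* their matched
    LAG (deposition had not yet happened by that date); ``upper_bound``
    from injections *coincident* with their LAG (deposition was observed
    happening that late, and not later).  Injections that postdate their
    LAG bound only that individual and are surfaced in ``per_turtle``
    rather than averaged into the window.  Bounds are month/day pairs —
    deposition is an annual cycle, so the year is discarded.  A side
    with no supporting turtle is None (undetermined).
    """

    lower_bound: tuple[int, int] | None  # (month, day), exclusive
    upper_bound: tuple[int, int] | None  # (month, day), inclusive
    per_turtle: list[TimingClassification] = field(default_factory=list)
    nominal_doy: int = 91

    def _shift(self, doy: float) -> float:
        # order days within the annual cycle anchored opposite the
        # deposition season so the window never straddles the cut
        anchor = (self.nominal_doy + 183) % 365
        return (doy - anchor) % 365

    def contains_doy(self, doy: int) -> bool:
        """True if day-of-year ``doy`` falls inside the inferred window."""
        s = self._shift(doy)
        if self.lower_bound is not None:
            lo = self._shift(_month_day_to_doy(*self.lower_bound))
            if s <= lo:
                return False
        if self.upper_bound is not None:
            hi = self._shift(_month_day_to_doy(*self.upper_bound))
            if s > hi:
                return False
        return self.lower_bound is not None or self.upper_bound is not None


def _month_day_to_doy(month: int, day: int) -> int:
    return (dt.date(2001, month, day) - dt.date(2001, 1, 1)).days + 1  # non-leap

def classify_deposition(
    scl_from_otc: float,
    scl_from_lag: float,
    tolerance: float = DEFAULT_COINCIDENCE_TOLERANCE_CM,
) -> Relation:
    """Relate LAG deposition to the OTC injection via back-calculated SCLs.

    A LAG back-calculating *smaller* than the OTC mark was laid down when
    the animal was smaller, i.e. before the injection; larger means after;
    within ``tolerance`` means the two marks are indistinguishable
    (deposition approximately coincident with injection).
    """
    if tolerance < 0:
        raise ParameterError(f"tolerance must be >= 0, got {tolerance}")
    delta = scl_from_lag - scl_from_otc
    if abs(delta) <= tolerance:
        return Relation.COINCIDENT
    return Relation.LAG_BEFORE_INJECTION if delta < 0 else Relation.LAG_AFTER_INJECTION


def infer_deposition_window(
    classifications: list[TimingClassification],
    nominal_doy: int = 91,
) -> DepositionWindow:
    """Bracket the deposition season from per-turtle OTC/LAG relations.

    * Injections whose matched LAG formed *after* them show deposition had
      not yet occurred: the latest such date (in season order) is the
      exclusive lower bound.
    * Injections *coincident* with their LAG show deposition happening at
      that date: the latest such date is the inclusive upper bound.
    * Injections whose LAG formed *before* them only say that individual
      had already deposited; they are reported per-turtle (individual
      variability), not folded into the population window.
    """
    if not classifications:
        raise DegenerateSampleError("no timing classifications to infer a window from")

    anchor = (nominal_doy + 183) % 365

    def season_pos(d: dt.date) -> float:
        return ((d.timetuple().tm_yday) - anchor) % 365

    lower_dates = [
        c.injection_date for c in classifications
        if c.relation is Relation.LAG_AFTER_INJECTION
    ]
    upper_dates = [
        c.injection_date for c in classifications
        if c.relation is Relation.COINCIDENT
    ]
    lower = max(lower_dates, key=season_pos) if lower_dates else None
    upper = max(upper_dates, key=season_pos) if upper_dates else None
    return DepositionWindow(
        lower_bound=(lower.month, lower.day) if lower else None,
        upper_bound=(upper.month, upper.day) if upper else None,
        per_turtle=list(classifications),
        nominal_doy=nominal_doy,
    )


def otc_fallback_length(
    otc_diameter: float | None,
    profile: BoneProfile,
    record: TurtleRecord,
    params: BackCalcParams | None = None,
) -> float:
    """Back-calculate SCL from the OTC-mark diameter.

    Used both for the OTC column of the timing comparison and as the
    estimate of SCL at tagging when the tagging-era LAG has been
    destroyed by the resorption core.
    """
    d = otc_diameter if otc_diameter is not None else profile.otc_diameter
    if d is None:
        raise DataAvailabilityError(
            f"{record.id}: no OTC mark diameter available for fallback"
        )
    return back_calculate_length(d, profile.section_diameter, record.scl_at_recovery, params)
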
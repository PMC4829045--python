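"""Calendar-year assignment to growth marks.

Growth marks are annual, deposited in a spring window (after December,
by mid-May).  The most recent calendar year belongs to the LAG closest
to the outer circumference of the bone; earlier LAGs count back one
year each.  Whether the outermost LAG carries the stranding year or the
previous year depends on where the stranding date falls relative to the
deposition season and on whether measurable bone growth separates the
final LAG from the section edge.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum

from .errors import EmptyProfileError, LagResorbedError, StructuralError

__all__ = [
    "DepositionSeason",
    "AssignmentBasis",
    "YearAssignment",
    "collapse_double_lags",
    "assign_lag_years",
    "select_lag_nearest_date",
    "nominal_deposition_date",
]


@dataclass(frozen=True)
class DepositionSeason:
    """Seasonal window in which annual LAGs are deposited.

    Defaults encode spring deposition: the window opens after December
    (month 1) and closes mid-May, with a nominal (population-typical)
    deposition day-of-year of 91 (~1 April), the midpoint of the window.
    """

    start_month: int = 1
    end_month: int = 5
    end_day: int = 15
    nominal_doy: int = 91

    def nominal_date(self, year: int) -> dt.date:
        return dt.date(year, 1, 1) + dt.timedelta(days=self.nominal_doy - 1)

    def end_date(self, year: int) -> dt.date:
        return dt.date(year, self.end_month, self.end_day)


class AssignmentBasis(str, Enum):
    EDGE_SAME_YEAR = "edge_same_year"
    EDGE_PREVIOUS_YEAR = "edge_previous_year"
    COUNTED_BACK = "counted_back"


@dataclass(frozen=True)
class YearAssignment:
    lag_index: int  # index into the collapsed LAG list, innermost = 0
    calendar_year: int
    basis: AssignmentBasis


def collapse_double_lags(
    diameters: list[float], double_flags: list[bool]
) -> list[float]:
    """Replace each flagged adjacent pair of lines by its outer (larger) member.

    Double LAGs — two closely spaced lines laid down within one annual
    cycle — are read as a single annual mark.  Flags must cover adjacent
    pairs; a run of flagged lines of odd length is malformed.
    """
    if len(diameters) != len(double_flags):
        raise StructuralError(
            f"{len(diameters)} diameters but {len(double_flags)} double flags"
        )
    out: list[float] = []
    i = 0
    n = len(diameters)
    while i < n:
        if not double_flags[i]:
            out.append(diameters[i])
            i += 1
            continue
        j = i
        while j < n and double_flags[j]:
            j += 1
        run = j - i
        if run % 2 != 0:
            raise StructuralError(
                f"run of {run} flagged lines starting at index {i}: "
                "double LAGs must be flagged in adjacent pairs"
            )
        for k in range(i, j, 2):  # keep the outer line of each pair
            out.append(max(diameters[k], diameters[k + 1]))
        i = j
    if any(b <= a for a, b in zip(out, out[1:])):
        raise StructuralError("collapsed diameters are not strictly increasing")
    return out


def assign_lag_years(
    n_lags: int,
    date_stranded: dt.date,
    edge_growth_present: bool,
    season: DepositionSeason | None = None,
) -> list[YearAssignment]:
    """Assign calendar years to ``n_lags`` collapsed LAGs, innermost to outermost.

    The outermost LAG carries

    * the previous calendar year when the turtle stranded before the
      nominal deposition date (that year's LAG cannot have formed yet);
    * the stranding year when stranding falls between the nominal
      deposition date and the end of the window and the final LAG sits
      at the bone edge (little/no differentiation), the previous year
      if measurable edge growth separates them;
    * the stranding year when stranding falls after the window closes
      (that spring's LAG is present regardless of edge growth).

    Remaining LAGs count back by one year per mark.
    """
    if n_lags < 1:
        raise EmptyProfileError("cannot assign years to a profile with no LAGs")
    season = season or DepositionSeason()
    y = date_stranded.year
    if date_stranded < season.nominal_date(y):
        outer_year, basis = y - 1, AssignmentBasis.EDGE_PREVIOUS_YEAR
    elif date_stranded <= season.end_date(y):
        if edge_growth_present:
            outer_year, basis = y - 1, AssignmentBasis.EDGE_PREVIOUS_YEAR
        else:
            outer_year, basis = y, AssignmentBasis.EDGE_SAME_YEAR
    else:
        outer_year, basis = y, AssignmentBasis.EDGE_SAME_YEAR
    out = []
    for i in range(n_lags):
        year = outer_year - (n_lags - 1 - i)
        b = basis if i == n_lags - 1 else AssignmentBasis.COUNTED_BACK
        out.append(YearAssignment(lag_index=i, calendar_year=year, basis=b))
    return out


def nominal_deposition_date(year: int, season: DepositionSeason | None = None) -> dt.date:
    """Nominal deposition date (season midpoint) of the LAG assigned to ``year``."""
    return (season or DepositionSeason()).nominal_date(year)


def _nearest_deposition_year(target: dt.date, season: DepositionSeason) -> int:
    """Calendar year whose nominal deposition date is closest to ``target``.

    Ties break toward the later year.
    """
    best_year, best_dist = None, None
    for y in (target.year - 1, target.year, target.year + 1):
        dist = abs((season.nominal_date(y) - target).days)
        if best_dist is None or dist <= best_dist:
            best_year, best_dist = y, dist
    return best_year


def select_lag_nearest_date(
    assignments: list[YearAssignment],
    target_date: dt.date,
    season: DepositionSeason | None = None,
) -> int:
    """Index of the LAG whose nominal deposition date is nearest ``target_date``.

    Ties break toward the later (outer) LAG.  If the year the target
    date truly belongs to precedes the earliest surviving LAG — i.e.
    that year's mark was destroyed by the resorption core —
    :class:`LagResorbedError` is raised so the caller can fall back to
    the OTC mark.
    """
    if not assignments:
        raise EmptyProfileError("no LAGs to select from")
    season = season or DepositionSeason()
    ideal = _nearest_deposition_year(target_date, season)
    earliest = min(a.calendar_year for a in assignments)
    if ideal < earliest:
        raise LagResorbedError(
            f"the {ideal} LAG nearest {target_date} lies within the resorption "
            f"core (earliest surviving LAG is {earliest}); use the OTC mark"
        )
    best_idx, best_dist = None, None
    for a in assignments:
        dist = abs((season.nominal_date(a.calendar_year) - target_date).days)
        if best_dist is None or dist <= best_dist:
            best_idx, best_dist = a.lag_index, dist
    return best_idx
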
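"""Domain types shared by all pipeline stages.

Unit conventions are fixed globally: carapace lengths (SCL, straightline
carapace length) are in centimetres; bone diameters are in millimetres;
dates are calendar dates; elapsed time is day-count / 365.25 years.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

__all__ = [
    "BackCalcParams",
    "TurtleRecord",
    "BoneProfile",
    "GrowthHistory",
    "ValidationReport",
    "validate_record",
    "elapsed_years",
]

DAYS_PER_YEAR = 365.25


def elapsed_years(start: dt.date, end: dt.date) -> float:
    """Elapsed time between two calendar dates, in years (day count / 365.25)."""
    return (end - start).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class BackCalcParams:
    """Constants of the body-proportional back-calculation equation.

    The allometric mean relationship between humerus diameter ``D`` (mm)
    and carapace length (cm) is ``L_op + b * (D - D_op) ** c`` where
    ``L_op`` is the average hatchling SCL, ``D_op`` the minimum hatchling
    humerus diameter, ``b`` the slope and ``c`` the proportionality
    coefficient.  Defaults are the published values for Hawaiian green
    turtles (fit over 36.4-97.9 cm SCL).
    """

    hatchling_length: float = 5.1  # L_op, cm
    hatchling_diameter: float = 2.6  # D_op, mm
    slope: float = 3.127  # b, cm per mm**c
    exponent: float = 0.928  # c, dimensionless

    def __post_init__(self) -> None:
        if not self.hatchling_length > 0:
            raise ValueError("hatchling_length must be > 0")
        if not self.hatchling_diameter > 0:
            raise ValueError("hatchling_diameter must be > 0")
        if not self.slope > 0:
            raise ValueError("slope must be > 0")
        if not 0 < self.exponent <= 2:
            raise ValueError("exponent must be in (0, 2]")

    def mean_length(self, diameter_mm: float) -> float:
        """Mean-allometry SCL (cm) at a given humerus diameter (mm)."""
        return self.hatchling_length + self.slope * (
            (diameter_mm - self.hatchling_diameter) ** self.exponent
        )

    def mean_diameter(self, length_cm: float) -> float:
        """Inverse of :meth:`mean_length`: humerus diameter (mm) at a mean-allometry SCL."""
        return self.hatchling_diameter + (
            (length_cm - self.hatchling_length) / self.slope
        ) ** (1.0 / self.exponent)


@dataclass
class TurtleRecord:
    """One individual's capture / tagging / OTC / stranding history.

    Negative observed growth (recovery SCL below tagging SCL) is valid
    data, not an invariant violation: emaciated turtles can shrink and
    observers mismeasure.
    """

    id: str
    date_tagged: dt.date
    scl_at_tagging: float  # cm, measured in the field at tagging
    date_stranded: dt.date
    scl_at_recovery: float  # cm, L_final, measured at dead recovery
    date_otc: dt.date | None = None  # oxytetracycline injection date
    fibropapilloma: bool = False


@dataclass
class BoneProfile:
    """Measured growth-mark diameters for one humerus cross-section.

    ``lag_diameters`` are ordered innermost to outermost, in mm, as read
    off the stained section along an axis parallel to the dorsal edge.
    ``double_flags`` marks members of closely spaced double LAGs (two
    lines deposited within one annual cycle, read as a single annual
    mark).  ``section_diameter`` is the full cross-section diameter
    ``D_final`` anchoring the back-calculation; ``otc_diameter`` is the
    diameter of the fluorescent oxytetracycline mark when visible.
    """

    turtle_id: str
    lag_diameters: list[float]
    section_diameter: float  # D_final, mm
    double_flags: list[bool] = field(default_factory=list)
    resorption_core_diameter: float = 0.0  # mm; LAGs below this were destroyed
    otc_diameter: float | None = None

    def __post_init__(self) -> None:
        if not self.double_flags:
            self.double_flags = [False] * len(self.lag_diameters)


@dataclass
class GrowthHistory:
    """Per-calendar-year back-calculated SCLs and annual growth rates."""

    turtle_id: str
    entries: list[tuple[int, float]]  # (calendar year, back-calculated SCL cm)
    annual_growth_rates: list[tuple[tuple[int, int], float]]  # ((y0, y1), cm/yr)


@dataclass
class ValidationReport:
    """Comparison of measured vs back-calculated SCLs with the test statistics."""

    per_turtle: list[tuple[str, float, float, float]]  # (id, measured, estimated, diff)
    wilcoxon_T: float
    wilcoxon_N: int
    wilcoxon_p: float
    mean_abs_difference: float  # cm, rounded to 0.1
    standard_error: float  # cm, SE of |differences|
    summary: dict[str, tuple[float, float, float, float]]  # column -> (mean, sd, min, max)


def _check_profile(profile: BoneProfile, issues: list[str]) -> None:
    from .chronology import collapse_double_lags  # local import avoids a cycle

    if len(profile.double_flags) != len(profile.lag_diameters):
        issues.append(
            f"{profile.turtle_id}: double_flags length {len(profile.double_flags)} "
            f"!= lag_diameters length {len(profile.lag_diameters)}"
        )
        return
    try:
        collapsed = collapse_double_lags(profile.lag_diameters, profile.double_flags)
    except Exception as exc:  # malformed flags reported as an issue, not raised
        issues.append(f"{profile.turtle_id}: double-LAG structure invalid: {exc}")
        return
    if any(b >= a for a, b in zip(collapsed[1:], collapsed[:-1])):
        issues.append(
            f"{profile.turtle_id}: collapsed LAG diameters are not strictly increasing"
        )
    for d in profile.lag_diameters:
        if d <= profile.resorption_core_diameter:
            issues.append(
                f"{profile.turtle_id}: LAG diameter {d} mm is not above the "
                f"resorption core ({profile.resorption_core_diameter} mm)"
            )
        if d >= profile.section_diameter:
            issues.append(
                f"{profile.turtle_id}: LAG diameter {d} mm is not below the "
                f"section diameter ({profile.section_diameter} mm)"
            )
    if profile.otc_diameter is not None and profile.otc_diameter >= profile.section_diameter:
        issues.append(
            f"{profile.turtle_id}: OTC mark diameter {profile.otc_diameter} mm is "
            f"not below the section diameter ({profile.section_diameter} mm)"
        )


def validate_record(record: TurtleRecord, profile: BoneProfile | None = None) -> list[str]:
    """Check type invariants; return one human-readable issue per violation.

    Diagnostic only: never raises for invariant violations, never mutates
    its inputs, and returns an empty list when everything holds.
    """
    issues: list[str] = []
    if record.date_tagged > record.date_stranded:
        issues.append(
            f"{record.id}: date_tagged {record.date_tagged} is after "
            f"date_stranded {record.date_stranded}"
        )
    if record.scl_at_tagging <= 0:
        issues.append(f"{record.id}: scl_at_tagging must be > 0")
    if record.scl_at_recovery <= 0:
        issues.append(f"{record.id}: scl_at_recovery must be > 0")
    if record.date_otc is not None:
        if not (record.date_tagged <= record.date_otc <= record.date_stranded):
            issues.append(
                f"{record.id}: date_otc {record.date_otc} outside "
                f"[date_tagged, date_stranded]"
            )
    if profile is not None:
        if profile.turtle_id != record.id:
            issues.append(
                f"profile turtle_id {profile.turtle_id!r} does not match record id "
                f"{record.id!r}"
            )
        _check_profile(profile, issues)
    return issues
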
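"""Body-proportional back-calculation of carapace length from mark diameters.

The body proportional hypothesis (BPH) assumes each individual's carapace
length deviates from the population's mean bone-body allometry by a
constant proportional factor throughout life.  Anchoring that factor at
dead recovery (``D_final``, ``L_final``) gives the estimated SCL at any
interior mark diameter ``D``::

    L = [L_op + b (D - D_op)^c] * L_final / [L_op + b (D_final - D_op)^c]

with hatchling anchors ``L_op`` (cm), ``D_op`` (mm), slope ``b`` and
proportionality coefficient ``c``.  The ratio form guarantees
``L(D_final) = L_final`` exactly and linear scaling in ``L_final``.
"""

from __future__ import annotations

from .core import BackCalcParams, BoneProfile, GrowthHistory, TurtleRecord
from .errors import AlignmentError, DomainError

__all__ = ["back_calculate_length", "invert_length_to_diameter", "growth_history"]


def back_calculate_length(
    mark_diameter: float,
    section_diameter: float,
    recovery_length: float,
    params: BackCalcParams | None = None,
) -> float:
    """Estimate SCL (cm) at the time a mark of diameter ``mark_diameter`` was laid down.

    Parameters
    ----------
    mark_diameter : float
        Diameter ``D`` of the growth mark of interest, mm.  Must lie in
        ``[D_op, D_final]``; marks are never extrapolated beyond the
        section edge.
    section_diameter : float
        Full cross-section diameter ``D_final``, mm.
    recovery_length : float
        SCL measured at dead recovery, ``L_final``, cm.
    params : BackCalcParams, optional
        Allometric constants; defaults to the published Hawaiian
        green-turtle fit.

    Returns
    -------
    float
        Estimated SCL in cm, at full precision (round only for reporting).
    """
    p = params or BackCalcParams()
    if recovery_length <= 0:
        raise DomainError(f"recovery_length must be > 0, got {recovery_length}")
    if mark_diameter < p.hatchling_diameter:
        raise DomainError(
            f"mark diameter {mark_diameter} mm is below the hatchling diameter "
            f"D_op = {p.hatchling_diameter} mm"
        )
    if mark_diameter > section_diameter:
        raise DomainError(
            f"mark diameter {mark_diameter} mm exceeds the section diameter "
            f"D_final = {section_diameter} mm (no extrapolation)"
        )
    # ratio first: the identity L(D_final) = L_final is then bit-exact
    return (p.mean_length(mark_diameter) / p.mean_length(section_diameter)) * recovery_length


def invert_length_to_diameter(
    length: float,
    section_diameter: float,
    recovery_length: float,
    params: BackCalcParams | None = None,
) -> float:
    """Analytic inverse of :func:`back_calculate_length`.

    Returns the mark diameter (mm) whose back-calculated SCL equals
    ``length``.  ``length`` must lie in the attainable image
    ``[L(D_op), L_final]``.
    """
    p = params or BackCalcParams()
    if recovery_length <= 0:
        raise DomainError(f"recovery_length must be > 0, got {recovery_length}")
    denom = p.mean_length(section_diameter)
    lo = p.hatchling_length * recovery_length / denom  # L at D = D_op
    if length < lo or length > recovery_length:
        raise DomainError(
            f"length {length} cm is outside the attainable interval "
            f"[{lo:.6g}, {recovery_length}] cm"
        )
    mean_l = length * denom / recovery_length  # undo the proportional anchoring
    return p.mean_diameter(mean_l)


def growth_history(
    profile: BoneProfile,
    years: list[int],
    record: TurtleRecord,
    params: BackCalcParams | None = None,
) -> GrowthHistory:
    """Back-calculate one SCL per (collapsed) LAG and derive annual growth rates.

    ``years`` must align 1:1 with the collapsed LAG diameters, innermost
    to outermost.  Growth rates are successive SCL differences over
    consecutive calendar years; a gap in years produces no rate entry.
    """
    from .chronology import collapse_double_lags

    collapsed = collapse_double_lags(profile.lag_diameters, profile.double_flags)
    if len(years) != len(collapsed):
        raise AlignmentError(
            f"{profile.turtle_id}: {len(years)} years given for "
            f"{len(collapsed)} collapsed LAGs"
        )
    entries = [
        (year, back_calculate_length(d, profile.section_diameter,
                                     record.scl_at_recovery, params))
        for year, d in zip(years, collapsed)
    ]
    rates = [
        ((y0, y1), l1 - l0)
        for (y0, l0), (y1, l1) in zip(entries, entries[1:])
        if y1 - y0 == 1
    ]
    return GrowthHistory(profile.turtle_id, entries, rates)
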
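"""Validation statistics for measured vs back-calculated carapace lengths.

The central test is a paired Wilcoxon signed-rank test computed exactly:
zero differences are dropped (Wilcoxon's original rule), absolute
differences are ranked with midranks for ties, the statistic ``T`` is
the smaller of the positive- and negative-rank sums, and the two-sided
p-value is the exact tail probability of the null distribution obtained
by enumerating all ``2^N`` equiprobable sign assignments of the observed
midrank vector.  For ``N > 25`` a tie-corrected normal approximation
with continuity correction takes over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import AlignmentError, DegenerateSampleError

__all__ = [
    "PairedDiffSet",
    "WilcoxonResult",
    "round_half_away",
    "paired_differences",
    "wilcoxon_signed_rank",
    "mean_absolute_difference",
    "standard_error",
    "column_summary",
]

_EXACT_LIMIT = 25  # exact enumeration up to this N; normal approximation beyond


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed field tables).

    ``round_half_away(-0.15) == -0.2`` whereas banker's rounding gives -0.1.
    """
    scale = 10.0**decimals
    # small epsilon absorbs binary representation error in .x5 values
    return math.copysign(math.floor(abs(x) * scale + 0.5 + 1e-9), x) / scale


@dataclass(frozen=True)
class PairedDiffSet:
    """Paired differences (measured - estimated), rounded to 0.1 cm.

    Rounding to the table's reporting precision happens *before* any
    statistic, matching how the printed difference columns were analysed.
    """

    ids: tuple[str, ...]
    differences: tuple[float, ...]

    def subset(self, exclude_ids: Sequence[str]) -> "PairedDiffSet":
        keep = [(i, d) for i, d in zip(self.ids, self.differences) if i not in exclude_ids]
        return PairedDiffSet(tuple(i for i, _ in keep), tuple(d for _, d in keep))


class WilcoxonResult(NamedTuple):
    T: float  # min(sum of positive ranks, sum of negative ranks)
    N: int  # pairs remaining after zero differences are dropped
    p: float  # exact (or approximate, N > 25) two-sided probability


def paired_differences(
    measured: Sequence[float],
    estimated: Sequence[float],
    ids: Sequence[str] | None = None,
) -> PairedDiffSet:
    """Element-wise measured - estimated, rounded half-away-from-zero to 0.1 cm."""
    if len(measured) != len(estimated):
        raise AlignmentError(
            f"{len(measured)} measured values vs {len(estimated)} estimated"
        )
    if ids is not None and len(ids) != len(measured):
        raise AlignmentError(f"{len(ids)} ids for {len(measured)} pairs")
    if ids is None:
        ids = [str(k) for k in range(len(measured))]
    diffs = tuple(round_half_away(m - e, 1) for m, e in zip(measured, estimated))
    return PairedDiffSet(tuple(ids), diffs)


def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of subsets of ``ranks2`` (doubled midranks, ints) by subset sum.

    The null distribution of the positive-rank sum assigns each of the
    2^N sign vectors equal probability; the count vector enumerates them
    by the resulting (doubled) rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(diffs: PairedDiffSet | Sequence[float]) -> WilcoxonResult:
    """Exact paired Wilcoxon signed-rank test with midranks and dropped zeros.

    Returns ``(T, N, p)`` where ``T = min(T+, T-)``, ``N`` counts the
    nonzero differences and ``p`` is the two-sided tail probability
    ``P(W+ <= T) + P(W+ >= S - T)`` with ``S = N(N+1)/2`` the total rank
    sum, computed from the exact enumeration distribution of the
    observed midrank vector (capped at 1).
    """
    d = np.asarray(
        diffs.differences if isinstance(diffs, PairedDiffSet) else diffs, dtype=float
    )
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = rankdata(np.abs(d))  # midranks for ties
    t_plus = float(ranks[d > 0].sum())
    t_minus = float(ranks[d < 0].sum())
    t = min(t_plus, t_minus)
    total = n * (n + 1) / 2.0
    if n <= _EXACT_LIMIT:
        ranks2 = np.rint(2.0 * ranks).astype(np.int64)  # midranks are k/2
        counts = _signed_rank_distribution(ranks2)
        t2 = int(math.floor(2.0 * t + 1e-9))
        lo = counts[: t2 + 1].sum()
        hi = counts[int(math.ceil(2.0 * (total - t) - 1e-9)):].sum()
        p = min(1.0, (lo + hi) / 2.0**n)
    else:
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        z = (t - total / 2.0 + 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * norm.cdf(z))
    return WilcoxonResult(T=t, N=n, p=float(p))


def mean_absolute_difference(
    diffs: PairedDiffSet, exclude_ids: Sequence[str] | None = None
) -> float:
    """Mean of |differences| in cm, rounded to 0.1 for reporting."""
    ds = diffs.subset(exclude_ids) if exclude_ids else diffs
    if not ds.differences:
        raise DegenerateSampleError("no differences left after exclusions")
    return round_half_away(float(np.mean(np.abs(ds.differences))), 1)


def standard_error(values: Sequence[float]) -> float:
    """Standard error of the absolute values: sd(|v|, n-1 denominator) / sqrt(n)."""
    v = np.abs(np.asarray(values, dtype=float))
    if v.size < 2:
        raise DegenerateSampleError("standard error needs at least 2 values")
    return float(v.std(ddof=1) / math.sqrt(v.size))


def column_summary(values: Sequence[float]) -> tuple[float, float, float, float]:
    """(mean, sample SD, min, max) of a column, each reported to 0.1 cm."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateSampleError("column summary needs at least 2 values")
    return (
        round_half_away(float(v.mean()), 1),
        round_half_away(float(v.std(ddof=1)), 1),
        round_half_away(float(v.min()), 1),
        round_half_away(float(v.max()), 1),
    )
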
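"""Transition/transversion statistics, exact 2x2 test, interval context.

The Fisher test is computed by exact hypergeometric enumeration in integer
arithmetic (no normal approximation, no floating-point tie comparisons):
all tables sharing the observed margins have probabilities with a common
denominator, so the two-sided point-probability criterion reduces to an
exact integer comparison.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from math import comb
from typing import Iterable, Mapping, Optional, Sequence

from famvar.core.types import IntervalTrack, VariantKey
from famvar.errors import FamvarError, NotApplicableError
from famvar.inheritance import COMMON, INDIVIDUAL, RecurrenceSummary

__all__ = [
    "TRANSITION",
    "TRANSVERSION",
    "classify_titv",
    "TiTvStratum",
    "TiTvTable",
    "titv_stratified",
    "FisherResult",
    "fisher_exact",
    "ContextAnnotation",
    "IntervalIndex",
    "annotate_context",
]

TRANSITION = "transition"
TRANSVERSION = "transversion"

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def classify_titv(ref: str, alt: str) -> str:
    """Classify a single-nucleotide substitution.

    Purine<->purine (A<->G) and pyrimidine<->pyrimidine (C<->T) changes are
    transitions; the eight purine<->pyrimidine changes are transversions.
    Strand-symmetric by construction.
    """
    ref_u, alt_u = ref.upper(), alt.upper()
    if len(ref_u) != 1 or len(alt_u) != 1 or ref_u == alt_u:
        raise NotApplicableError(f"Ti/Tv undefined for {ref!r}>{alt!r}")
    if {ref_u, alt_u} - (_PURINES | _PYRIMIDINES):
        raise NotApplicableError(f"non-ACGT substitution {ref!r}>{alt!r}")
    both_purine = ref_u in _PURINES and alt_u in _PURINES
    both_pyrimidine = ref_u in _PYRIMIDINES and alt_u in _PYRIMIDINES
    return TRANSITION if (both_purine or both_pyrimidine) else TRANSVERSION


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero (matches printed table rounding)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class TiTvStratum:
    ti: int
    tv: int

    @property
    def ratio(self) -> Optional[float]:
        """ti/tv rounded half-up to one decimal; None (NA) when tv == 0."""
        if self.tv == 0:
            return None
        return round_half_up(self.ti / self.tv, 1)


@dataclass
class TiTvTable:
    """Ti/Tv counts and ratios for the total/common/individual strata."""

    total: TiTvStratum
    common: TiTvStratum
    individual: TiTvStratum

    def stratum(self, name: str) -> TiTvStratum:
        return {"total": self.total, COMMON: self.common, INDIVIDUAL: self.individual}[name]


def titv_stratified(
    keys: Iterable[VariantKey],
    recurrence: RecurrenceSummary,
) -> TiTvTable:
    """Count transitions/transversions per recurrence stratum.

    Only single-nucleotide substitutions enter the counts; every SNV key
    must have a recurrence class.
    """
    counts = {"total": [0, 0], COMMON: [0, 0], INDIVIDUAL: [0, 0]}
    for key in keys:
        if not key.is_snv:
            continue
        kind = classify_titv(key.ref, key.alt)
        slot = 0 if kind == TRANSITION else 1
        counts["total"][slot] += 1
        stratum = recurrence.stratum_of(key)
        counts[stratum][slot] += 1
    return TiTvTable(
        total=TiTvStratum(*counts["total"]),
        common=TiTvStratum(*counts[COMMON]),
        individual=TiTvStratum(*counts[INDIVIDUAL]),
    )


# ---------------------------------------------------------------------------
# exact 2x2 test
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    """Exact test result for the 2x2 table ``[[a, b], [c, d]]``.

    ``p_two_sided`` follows the point-probability (Fisher) definition: the
    sum over all tables with the observed margins whose point probability
    does not exceed that of the observed table.  ``p_one_sided_greater`` is
    the upper tail on cell ``a``.
    """

    p_two_sided: float
    p_one_sided_greater: float
    table: tuple[int, int, int, int]
    point_probability: float


def fisher_exact(a: int, b: int, c: int, d: int) -> FisherResult:
    """Exact hypergeometric enumeration over all tables with fixed margins."""
    cells = (a, b, c, d)
    if any(x < 0 for x in cells) or any(not isinstance(x, int) for x in cells):
        raise FamvarError(f"cell counts must be non-negative integers, got {cells}")
    n = a + b + c + d
    if n < 1:
        raise FamvarError("table total must be >= 1")
    row1, row2, col1 = a + b, c + d, a + c
    # table with cell a = k has probability C(row1,k)C(row2,col1-k)/C(n,col1);
    # numerators are exact integers over the common denominator
    denominator = comb(n, col1)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    numerators = {k: comb(row1, k) * comb(row2, col1 - k) for k in range(lo, hi + 1)}
    observed = numerators[a]
    two_sided_num = sum(num for num in numerators.values() if num <= observed)
    greater_num = sum(num for k, num in numerators.items() if k >= a)
    return FisherResult(
        p_two_sided=two_sided_num / denominator,
        p_one_sided_greater=greater_num / denominator,
        table=cells,
        point_probability=observed / denominator,
    )


# ---------------------------------------------------------------------------
# genomic-context interval annotation
# ---------------------------------------------------------------------------

class IntervalIndex:
    """Point-in-interval lookup over a track (1-based, closed on both ends).

    Intervals are sorted by start per chromosome with a running maximum of
    interval ends, so a query walks back from the bisection point only
    while a covering interval is still possible.
    """

    def __init__(self, track: IntervalTrack):
        self.name = track.name
        self._by_chrom: dict[str, tuple[list[int], list, list[int]]] = {}
        grouped: dict[str, list] = {}
        for interval in track:
            grouped.setdefault(interval.chrom, []).append(interval)
        for chrom, intervals in grouped.items():
            intervals.sort(key=lambda iv: (iv.start, iv.end))
            starts = [iv.start for iv in intervals]
            max_end = []
            running = 0
            for iv in intervals:
                running = max(running, iv.end)
                max_end.append(running)
            self._by_chrom[chrom] = (starts, intervals, max_end)

    def find(self, chrom: str, pos: int):
        """Return the first covering interval (by start) or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, intervals, max_end = entry
        idx = bisect_right(starts, pos) - 1
        best = None
        while idx >= 0 and max_end[idx] >= pos:
            if intervals[idx].end >= pos:
                best = intervals[idx]
            idx -= 1
        return best


@dataclass
class ContextAnnotation:
    """Per-variant genomic-context membership, one label slot per track."""

    key: VariantKey
    hits: dict  # track name -> interval label (or None)

    @property
    def fragile_site(self) -> Optional[str]:
        return self.hits.get("fragile_sites")

    @property
    def in_structural_variation(self) -> bool:
        return self.hits.get("structural_variation") is not None

    @property
    def repeat_class(self) -> Optional[str]:
        return self.hits.get("repeats")


def annotate_context(
    keys: Sequence[VariantKey],
    tracks: Iterable[IntervalTrack],
) -> tuple[list[ContextAnnotation], dict]:
    """Annotate each variant position against every track.

    Membership is 1-based and inclusive on both interval ends.  Returns the
    per-variant annotations plus per-track hit counts.
    """
    indexes = [IntervalIndex(track) for track in tracks]
    annotations: list[ContextAnnotation] = []
    summary = {index.name: 0 for index in indexes}
    for key in keys:
        hits = {}
        for index in indexes:
            interval = index.find(key.chrom, key.pos)
            hits[index.name] = None if interval is None else (interval.label or "+")
            if interval is not None:
                summary[index.name] += 1
        annotations.append(ContextAnnotation(key=key, hits=hits))
    return annotations, summary
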
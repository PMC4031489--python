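"""Germline vs. de novo partitioning and recurrence/sharing summaries.

After paternal subtraction, every variant carried by a daughter has exactly
one explanation: inherited from the mother (*germline*) or absent from both
parents (*de novo*).  :func:`classify_pair` emits one record per
(variant, daughter); the summaries below reduce those records and the raw
presence matrix to the family-level counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from famvar.core.types import CohortCallset, VariantKey
from famvar.errors import PedigreeError

__all__ = [
    "InheritanceRecord",
    "PairSummary",
    "RecurrenceSummary",
    "classify_pair",
    "pair_summary",
    "recurrence_summary",
    "sister_sharing",
    "gene_set_overlap",
]

GERMLINE = "germline"
DE_NOVO = "de_novo"


@dataclass(frozen=True, order=True)
class InheritanceRecord:
    key: VariantKey
    daughter_id: str
    label: str  # GERMLINE | DE_NOVO


def classify_pair(
    callset: CohortCallset,
    mother_id: str,
    father_id: Optional[str],
    daughter_ids: Iterable[str],
) -> list[InheritanceRecord]:
    """Label each daughter-carried variant germline or de novo.

    Precondition: paternal removal has already been applied for these
    daughters.  A variant still present in both the father and a daughter
    violates that precondition and raises :class:`PedigreeError` rather
    than inventing a third label.
    """
    records: list[InheritanceRecord] = []
    for daughter in daughter_ids:
        for key in callset.sample_variants(daughter):
            carriers = callset.carriers(key)
            if father_id is not None and father_id in carriers:
                raise PedigreeError(
                    f"variant {key} present in father {father_id!r} and daughter "
                    f"{daughter!r}; paternal removal must run first"
                )
            label = GERMLINE if mother_id in carriers else DE_NOVO
            records.append(InheritanceRecord(key=key, daughter_id=daughter, label=label))
    return sorted(records)


@dataclass
class PairSummary:
    """Pair-level reduction of inheritance records.

    ``germline_count`` deduplicates across daughters: it is the number of
    distinct variants present in the mother and in at least one daughter.
    De novo events are counted per daughter.
    """

    germline_count: int
    de_novo_counts: dict[str, int]
    germline_keys: tuple[VariantKey, ...] = ()
    de_novo_keys: dict[str, tuple[VariantKey, ...]] = field(default_factory=dict)


def pair_summary(
    records: Iterable[InheritanceRecord],
    daughter_ids: Iterable[str],
) -> PairSummary:
    daughters = tuple(daughter_ids)
    germline_keys: set[VariantKey] = set()
    de_novo: dict[str, set[VariantKey]] = {d: set() for d in daughters}
    for record in records:
        if record.label == GERMLINE:
            germline_keys.add(record.key)
        else:
            de_novo.setdefault(record.daughter_id, set()).add(record.key)
    return PairSummary(
        germline_count=len(germline_keys),
        de_novo_counts={d: len(keys) for d, keys in de_novo.items()},
        germline_keys=tuple(sorted(germline_keys)),
        de_novo_keys={d: tuple(sorted(keys)) for d, keys in de_novo.items()},
    )


COMMON = "common"
INDIVIDUAL = "individual"


@dataclass
class RecurrenceSummary:
    """Per-variant carrier counts among affected members.

    ``frequency`` maps variant to its number of affected carriers; class
    ``common`` means frequency >= ``common_min``, ``individual`` means
    frequency == 1.  ``total_frequency`` is the sum over variants.
    """

    frequency: dict[VariantKey, int]
    classes: dict[VariantKey, str]
    common_min: int

    @property
    def total_frequency(self) -> int:
        return sum(self.frequency.values())

    @property
    def common_keys(self) -> tuple[VariantKey, ...]:
        return tuple(sorted(k for k, c in self.classes.items() if c == COMMON))

    @property
    def individual_keys(self) -> tuple[VariantKey, ...]:
        return tuple(sorted(k for k, c in self.classes.items() if c == INDIVIDUAL))

    def stratum_of(self, key: VariantKey) -> str:
        return self.classes[key]


def recurrence_summary(
    callset: CohortCallset,
    affected_ids: Iterable[str],
    recurrence_common_min: int = 2,
) -> RecurrenceSummary:
    """Count affected carriers per variant and assign recurrence classes.

    Only affected members enter the frequency; unaffected carriers are
    ignored by design.  Variants carried by no affected member are omitted.
    """
    affected = set(affected_ids)
    if not affected:
        raise ValueError("affected_ids must be non-empty")
    frequency: dict[VariantKey, int] = {}
    for key in callset.variants():
        count = len(callset.carriers(key) & affected)
        if count:
            frequency[key] = count
    classes = {
        k: (COMMON if n >= recurrence_common_min else INDIVIDUAL)
        for k, n in frequency.items()
    }
    return RecurrenceSummary(
        frequency=frequency, classes=classes, common_min=recurrence_common_min
    )


def sister_sharing(
    callset: CohortCallset, sister_ids: Sequence[str]
) -> dict:
    """Summarize sharing among sisters.

    Returns ``shared_ge2`` (variants present in at least two sisters) and
    ``exclusive`` (per sister, variants present in exactly that one sister).
    """
    sisters = tuple(sister_ids)
    shared_ge2 = 0
    exclusive = {s: 0 for s in sisters}
    exclusive_keys: dict[str, list[VariantKey]] = {s: [] for s in sisters}
    shared_keys: list[VariantKey] = []
    for key in callset.variants():
        carrying = [s for s in sisters if s in callset.carriers(key)]
        if len(carrying) >= 2:
            shared_ge2 += 1
            shared_keys.append(key)
        elif len(carrying) == 1:
            exclusive[carrying[0]] += 1
            exclusive_keys[carrying[0]].append(key)
    return {
        "shared_ge2": shared_ge2,
        "exclusive": exclusive,
        "shared_keys": tuple(shared_keys),
        "exclusive_keys": {s: tuple(v) for s, v in exclusive_keys.items()},
    }


def gene_set_overlap(genes_a: Iterable[str], genes_b: Iterable[str]) -> set[str]:
    """Exact-symbol intersection after case normalization.

    No fuzzy family matching: FOXP1 and FOXA1 do not match.  Returns
    uppercase symbols.
    """
    a = {g.strip().upper() for g in genes_a}
    b = {g.strip().upper() for g in genes_b}
    return a & b
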
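"""Core domain types.

The whole pipeline is keyed on :class:`VariantKey` (one normalized variant
site) and operates on :class:`CohortCallset`, a variant x sample x caller
presence matrix.  Zygosity is deliberately collapsed to presence/absence:
every downstream operation is a restriction of the matrix, and hemizygous
calls count as present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional

from famvar.errors import (
    ConfigError,
    InvalidAlleleError,
    InvalidVariantError,
    PedigreeError,
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: Chromosome aliases folded into the canonical "chr"-prefixed dialect.
_CHROM_ALIASES = {"MT": "M"}


def canonical_chrom(chrom: str) -> str:
    """Return *chrom* in the canonical ``chr``-prefixed dialect.

    ``"5"`` and ``"chr5"`` both map to ``"chr5"``; ``"MT"`` maps to
    ``"chrM"``; sex chromosomes are uppercased.
    """
    label = chrom.strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    if label.upper() in ("X", "Y", "M", "MT"):
        label = label.upper()
    label = _CHROM_ALIASES.get(label, label)
    return "chr" + label


@dataclass(frozen=True, order=True)
class VariantKey:
    """One normalized variant site; identity key for the whole system.

    Construct via :func:`normalize_key` (or the :meth:`of` alias) so the
    canonicalization invariants hold: ``chr``-prefixed chromosome,
    uppercase alleles, ``ref != alt``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @classmethod
    def of(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        return normalize_key(chrom, pos, ref, alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # e.g. "chr5:139936828 C>T"
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Normalize raw fields into a canonical :class:`VariantKey`.

    Idempotent: normalizing an already-normalized key is the identity.

    Raises
    ------
    InvalidAlleleError
        If either allele contains characters outside ``ACGT``.
    InvalidVariantError
        If ``pos < 1``, an allele is empty, or ``ref == alt`` after
        uppercasing.
    """
    if pos < 1:
        raise InvalidVariantError(f"position must be >= 1, got {pos}")
    ref_u, alt_u = ref.strip().upper(), alt.strip().upper()
    if not ref_u or not alt_u:
        raise InvalidVariantError("alleles must be non-empty")
    for allele in (ref_u, alt_u):
        if not _ALLELE_RE.match(allele):
            raise InvalidAlleleError(f"allele {allele!r} contains non-ACGT characters")
    if ref_u == alt_u:
        raise InvalidVariantError(
            f"ref and alt are identical ({ref_u}) at {chrom}:{pos}"
        )
    return VariantKey(canonical_chrom(chrom), int(pos), ref_u, alt_u)


class FunctionalClass(str, Enum):
    """Coding consequence of a variant, as carried by the annotation table."""

    synonymous = "synonymous"
    nonsynonymous_SNV = "nonsynonymous_SNV"
    splicing = "splicing"
    stopgain = "stopgain"
    stoploss = "stoploss"
    other = "other"

    @classmethod
    def parse(cls, text: str) -> "FunctionalClass":
        token = text.strip().replace(" ", "_").replace("-", "_")
        aliases = {
            "nonsynonymous_snv": cls.nonsynonymous_SNV,
            "nonsynonymous": cls.nonsynonymous_SNV,
            "stop_gain": cls.stopgain,
            "stop_loss": cls.stoploss,
        }
        low = token.lower()
        if low in aliases:
            return aliases[low]
        try:
            return cls(token)
        except ValueError:
            try:
                return cls[low]
            except KeyError:
                return cls.other


@dataclass
class VariantAnnotation:
    """Per-variant annotation: gene, consequence, catalog MAFs and scores.

    ``maf`` maps catalog name to minor allele frequency; an absent catalog
    entry means *not catalogued* (novel), never 0.0.  ``sift`` and
    ``polyphen_hvar`` may both be absent (e.g. stop-gain rows).
    """

    key: VariantKey
    gene: str
    cdna_change: str = ""
    protein_change: str = ""
    functional_class: FunctionalClass = FunctionalClass.other
    known_id: Optional[str] = None
    maf: Mapping[str, float] = field(default_factory=dict)
    sift: Optional[float] = None
    polyphen_hvar: Optional[float] = None
    sanger_confirmed: Optional[bool] = None

    def __post_init__(self) -> None:
        for catalog, value in self.maf.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"MAF {value} for catalog {catalog!r} outside [0,1]")

    @property
    def is_novel(self) -> bool:
        """True when the variant appears in no population catalog."""
        return len(self.maf) == 0

    @property
    def max_maf(self) -> Optional[float]:
        return max(self.maf.values()) if self.maf else None


@dataclass(frozen=True)
class Individual:
    """One pedigree member."""

    id: str
    sex: str  # "female" | "male" | "unknown"
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    affected: bool = False
    carrier: Optional[bool] = None
    age: Optional[float] = None


class Pedigree:
    """Family members with parent links, sex, and affection status.

    Parent links must reference existing members or be ``None`` (founder);
    no member may be its own ancestor.
    """

    def __init__(self, members: Iterable[Individual]):
        self._members: dict[str, Individual] = {}
        for m in members:
            if m.id in self._members:
                raise PedigreeError(f"duplicate member id {m.id!r}")
            self._members[m.id] = m
        self._validate()

    def _validate(self) -> None:
        for m in self._members.values():
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._members:
                    raise PedigreeError(
                        f"member {m.id!r} references missing parent {pid!r}"
                    )
        # ancestry must be acyclic
        state: dict[str, int] = {}

        def visit(mid: str, stack: tuple[str, ...]) -> None:
            if mid in stack:
                raise PedigreeError(f"pedigree cycle involving {mid!r}")
            if state.get(mid) == 2:
                return
            m = self._members[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid, stack + (mid,))
            state[mid] = 2

        for mid in self._members:
            visit(mid, ())

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __len__(self) -> int:
        return len(self._members)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._members

    def __getitem__(self, member_id: str) -> Individual:
        try:
            return self._members[member_id]
        except KeyError:
            raise PedigreeError(f"unknown pedigree member {member_id!r}") from None

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._members)

    @property
    def affected_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self if m.affected)

    @property
    def unaffected_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self if not m.affected)

    @property
    def founder_ids(self) -> tuple[str, ...]:
        return tuple(
            m.id for m in self if m.father_id is None and m.mother_id is None
        )

    def children_of(self, parent_id: str) -> tuple[str, ...]:
        return tuple(
            m.id
            for m in self
            if parent_id in (m.father_id, m.mother_id)
        )

    def daughters_of(self, parent_id: str) -> tuple[str, ...]:
        return tuple(
            cid for cid in self.children_of(parent_id) if self[cid].sex == "female"
        )

    def is_parent(self, parent_id: str, child_id: str) -> bool:
        child = self[child_id]
        return parent_id in (child.father_id, child.mother_id)

    def topological_order(self) -> tuple[str, ...]:
        """Member ids ordered so every parent precedes its children."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(mid: str) -> None:
            if mid in seen:
                return
            m = self._members[mid]
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    visit(pid)
            seen.add(mid)
            order.append(mid)

        for mid in sorted(self._members):
            visit(mid)
        return tuple(order)


class CohortCallset:
    """Variant x sample x caller presence matrix.

    ``per_caller`` holds one ``{VariantKey: frozenset(sample ids)}`` map per
    caller; after :func:`~famvar.cascade.consensus_callers` the merged
    single-matrix view lives in ``merged``.  Absence is the default:
    presence entries are only ever stored as carrier sets, and restriction
    operations never add entries.
    """

    def __init__(
        self,
        samples: Iterable[str],
        per_caller: Optional[Mapping[str, Mapping[VariantKey, frozenset]]] = None,
        merged: Optional[Mapping[VariantKey, frozenset]] = None,
        meta: Optional[dict] = None,
    ):
        self.samples: tuple[str, ...] = tuple(samples)
        sample_set = set(self.samples)
        self.per_caller: dict[str, dict[VariantKey, frozenset]] = {}
        if per_caller:
            for caller, matrix in per_caller.items():
                self.per_caller[caller] = {
                    k: frozenset(carriers)
                    for k, carriers in matrix.items()
                    if carriers
                }
        self.merged: Optional[dict[VariantKey, frozenset]] = None
        if merged is not None:
            self.merged = {
                k: frozenset(carriers) for k, carriers in merged.items() if carriers
            }
        for matrix in list(self.per_caller.values()) + (
            [self.merged] if self.merged else []
        ):
            for carriers in matrix.values():
                unknown = set(carriers) - sample_set
                if unknown:
                    raise ConfigError(f"carriers reference unknown samples {unknown}")
        self.meta: dict = dict(meta or {})

    # -- constructors -------------------------------------------------
    @classmethod
    def from_merged(
        cls,
        samples: Iterable[str],
        carriers: Mapping[VariantKey, Iterable[str]],
        meta: Optional[dict] = None,
    ) -> "CohortCallset":
        return cls(
            samples,
            merged={k: frozenset(v) for k, v in carriers.items()},
            meta=meta,
        )

    # -- queries ------------------------------------------------------
    @property
    def callers(self) -> tuple[str, ...]:
        return tuple(self.per_caller)

    @property
    def is_merged(self) -> bool:
        return self.merged is not None

    def _require_merged(self) -> dict[VariantKey, frozenset]:
        if self.merged is None:
            raise ConfigError(
                "callset has per-caller matrices only; run consensus_callers first"
            )
        return self.merged

    def variants(self) -> tuple[VariantKey, ...]:
        if self.merged is not None:
            return tuple(sorted(self.merged))
        keys: set[VariantKey] = set()
        for matrix in self.per_caller.values():
            keys.update(matrix)
        return tuple(sorted(keys))

    def carriers(self, key: VariantKey) -> frozenset:
        return self._require_merged().get(key, frozenset())

    def present(self, key: VariantKey, sample: str, caller: Optional[str] = None) -> bool:
        if caller is not None:
            return sample in self.per_caller.get(caller, {}).get(key, frozenset())
        return sample in self.carriers(key)

    def sample_variants(self, sample: str) -> tuple[VariantKey, ...]:
        return tuple(
            sorted(k for k, c in self._require_merged().items() if sample in c)
        )

    # -- restrictions (never add entries) ------------------------------
    def restrict(self, keys: Iterable[VariantKey]) -> "CohortCallset":
        """Keep only the given variant keys."""
        keep = set(keys)
        per_caller = {
            caller: {k: v for k, v in matrix.items() if k in keep}
            for caller, matrix in self.per_caller.items()
        }
        merged = (
            {k: v for k, v in self.merged.items() if k in keep}
            if self.merged is not None
            else None
        )
        return CohortCallset(self.samples, per_caller, merged, meta=self.meta)

    def without_sample_presence(
        self, removals: Mapping[VariantKey, Iterable[str]]
    ) -> "CohortCallset":
        """Clear presence of given samples at given variants (merged view)."""
        merged = dict(self._require_merged())
        for key, samples in removals.items():
            if key in merged:
                remaining = merged[key] - frozenset(samples)
                if remaining:
                    merged[key] = remaining
                else:
                    del merged[key]
        return CohortCallset(self.samples, self.per_caller, merged, meta=self.meta)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortCallset):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.per_caller == other.per_caller
            and self.merged == other.merged
        )


@dataclass(frozen=True)
class Interval:
    """1-based, closed-interval genomic span with a label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class IntervalTrack:
    """Named collection of genomic intervals, stored 1-based closed."""

    name: str
    intervals: list[Interval] = field(default_factory=list)
    convention: str = "1-based-closed"

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class FilterConfig:
    """Thresholds and knobs for the prioritization cascade.

    Defaults encode the published bands: variants with any catalog
    MAF > 0.001 are common; SIFT < 0.05 is damaging; PolyPhen-2 HumVar
    >= 0.447 is possibly-damaging or worse.
    """

    maf_threshold: float = 0.001
    sift_damaging_max: float = 0.05
    polyphen_damaging_min: float = 0.447
    kept_classes: frozenset = frozenset(
        {
            FunctionalClass.nonsynonymous_SNV,
            FunctionalClass.splicing,
            FunctionalClass.stopgain,
            FunctionalClass.stoploss,
        }
    )
    caller_mode: str = "intersection"  # or "union"
    control_ids: tuple[str, ...] = ()
    recurrence_common_min: int = 2
    require_confirmation: bool = False
    #: caller-side quality knobs, provenance metadata only (never applied)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "sift_damaging_max", "polyphen_damaging_min"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {value}")
        if self.caller_mode not in ("intersection", "union"):
            raise ConfigError(f"unknown caller_mode {self.caller_mode!r}")
        if self.recurrence_common_min < 1:
            raise ConfigError("recurrence_common_min must be >= 1")
        self.kept_classes = frozenset(
            FunctionalClass.parse(c) if isinstance(c, str) else c
            for c in self.kept_classes
        )
        self.control_ids = tuple(self.control_ids)

    def validate_against(self, pedigree: Pedigree) -> None:
        for cid in self.control_ids:
            if cid not in pedigree:
                raise ConfigError(f"control id {cid!r} not in pedigree")

    def with_(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)
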
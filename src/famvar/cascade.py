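"""Six-stage family-based variant prioritization cascade.

Every stage is a pure restriction: the output variant set is a subset of
the input set, presence entries are never added, and each stage logs its
in/out counts plus the removed keys in a :class:`CascadeAudit`.

Stage order, composed by :func:`run_cascade`:

1. caller consensus (intersection by default, union configurable)
2. subtraction of variants shared with unaffected controls
3. minor-allele-frequency filter (rare or novel survive)
4. functional-class filter (nonsynonymous / splicing / stop gain / stop loss)
5. deleteriousness prediction (SIFT OR PolyPhen-2 band rule)
6. father-to-daughter transmitted-variant removal
7. optional confirmation filter on a provided validation flag
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from famvar.core.types import (
    CohortCallset,
    FilterConfig,
    FunctionalClass,
    Pedigree,
    VariantAnnotation,
    VariantKey,
)
from famvar.errors import ConfigError, MissingAnnotationError, PedigreeError

__all__ = [
    "CascadeAudit",
    "CascadeResult",
    "consensus_callers",
    "remove_shared_with_unaffected",
    "filter_functional_class",
    "filter_rare",
    "predict_deleterious",
    "remove_paternal",
    "run_cascade",
]


@dataclass
class StageRecord:
    stage: str
    variants_in: int
    variants_out: int
    removed_keys: tuple[VariantKey, ...]

    def __post_init__(self) -> None:
        assert self.variants_out <= self.variants_in


@dataclass
class CascadeAudit:
    """Per-stage in/out counts and removed keys, in execution order."""

    stages: list[StageRecord] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(
        self,
        stage: str,
        before: Iterable[VariantKey],
        after: Iterable[VariantKey],
    ) -> None:
        before_set, after_set = set(before), set(after)
        self.stages.append(
            StageRecord(
                stage=stage,
                variants_in=len(before_set),
                variants_out=len(after_set),
                removed_keys=tuple(sorted(before_set - after_set)),
            )
        )

    def to_lines(self) -> list[str]:
        lines = [
            f"{s.stage}\tin={s.variants_in}\tout={s.variants_out}\tremoved={len(s.removed_keys)}"
            for s in self.stages
        ]
        lines.extend(f"# warning: {w}" for w in self.warnings)
        return lines


@dataclass
class CascadeResult:
    callset: CohortCallset
    audit: CascadeAudit

    @property
    def final_keys(self) -> tuple[VariantKey, ...]:
        return self.callset.variants()


# ---------------------------------------------------------------------------
# stage 1: caller consensus
# ---------------------------------------------------------------------------

def consensus_callers(callset: CohortCallset, mode: str = "intersection") -> CohortCallset:
    """Merge per-caller matrices into one presence matrix.

    ``intersection`` keeps a (variant, sample) entry only when every caller
    reports it; ``union`` keeps entries reported by any caller.  A callset
    that is already merged (or has a single caller) passes through with its
    matrix unchanged.
    """
    if mode not in ("intersection", "union"):
        raise ConfigError(f"unknown caller mode {mode!r}")
    if not callset.per_caller:
        if callset.is_merged:
            return CohortCallset(callset.samples, merged=callset.merged, meta=callset.meta)
        raise ConfigError("callset has no caller matrices")
    matrices = list(callset.per_caller.values())
    keys: set[VariantKey] = set()
    for m in matrices:
        keys.update(m)
    merged: dict[VariantKey, frozenset] = {}
    for key in keys:
        carrier_sets = [m.get(key, frozenset()) for m in matrices]
        if mode == "intersection":
            carriers = frozenset.intersection(*map(frozenset, carrier_sets))
        else:
            carriers = frozenset().union(*carrier_sets)
        if carriers:
            merged[key] = carriers
    return CohortCallset(callset.samples, merged=merged, meta=callset.meta)


# ---------------------------------------------------------------------------
# stage 2: unaffected-control subtraction
# ---------------------------------------------------------------------------

def remove_shared_with_unaffected(
    callset: CohortCallset,
    pedigree: Pedigree,
    control_ids: Iterable[str],
) -> CohortCallset:
    """Drop every variant carried by any unaffected control.

    Additionally drops variants carried by no affected member, so the
    surviving set is strictly affected-only.
    """
    controls = tuple(control_ids)
    if not controls:
        raise ConfigError("control_ids must be non-empty")
    for cid in controls:
        if pedigree[cid].affected:
            raise ConfigError(f"control {cid!r} is marked affected")
    affected = set(pedigree.affected_ids) & set(callset.samples)
    keep = [
        key
        for key in callset.variants()
        if not (callset.carriers(key) & set(controls))
        and (callset.carriers(key) & affected)
    ]
    return callset.restrict(keep)


# ---------------------------------------------------------------------------
# stages 3-5: annotation-driven restrictions
# ---------------------------------------------------------------------------

def filter_rare(
    annotations: Mapping[VariantKey, VariantAnnotation],
    maf_threshold: float = 0.001,
) -> dict[VariantKey, VariantAnnotation]:
    """Keep novel variants and catalogued variants with max MAF <= threshold."""
    return {
        key: ann
        for key, ann in annotations.items()
        if ann.is_novel or (ann.max_maf is not None and ann.max_maf <= maf_threshold)
    }


def filter_functional_class(
    annotations: Mapping[VariantKey, VariantAnnotation],
    kept_classes: Iterable[FunctionalClass],
) -> dict[VariantKey, VariantAnnotation]:
    """Keep only the requested consequence classes (drops synonymous/other)."""
    kept = frozenset(kept_classes)
    return {k: a for k, a in annotations.items() if a.functional_class in kept}


def predict_deleterious(
    annotation: VariantAnnotation,
    config: FilterConfig,
    audit: Optional[CascadeAudit] = None,
) -> bool:
    """Apply the score-band OR rule for predicted loss of function.

    Stop gain/loss and splicing variants are deleterious unconditionally.
    A nonsynonymous variant is deleterious when SIFT calls it damaging
    (score < ``sift_damaging_max``) or PolyPhen-2 HumVar calls it at least
    possibly damaging (score >= ``polyphen_damaging_min``), or both.  A
    nonsynonymous variant with both scores absent is conservatively kept
    out (returns False) with a warning.
    """
    cls = annotation.functional_class
    if cls in (FunctionalClass.stopgain, FunctionalClass.stoploss, FunctionalClass.splicing):
        return True
    sift, polyphen = annotation.sift, annotation.polyphen_hvar
    if sift is None and polyphen is None:
        if audit is not None:
            audit.warnings.append(
                f"no deleteriousness scores for {annotation.key} ({annotation.gene})"
            )
        return False
    if sift is not None and sift < config.sift_damaging_max:
        return True
    if polyphen is not None and polyphen >= config.polyphen_damaging_min:
        return True
    return False


# ---------------------------------------------------------------------------
# stage 6: paternal-transmission removal
# ---------------------------------------------------------------------------

def remove_paternal(
    callset: CohortCallset,
    pedigree: Pedigree,
    father_id: str,
    daughter_ids: Iterable[str],
) -> CohortCallset:
    """Clear daughter presence for variants the daughter shares with her father.

    Presence is edited per daughter; other carriers of the same variant are
    untouched.  Variants left with no carriers are dropped.
    """
    daughters = tuple(daughter_ids)
    for did in daughters:
        if pedigree[did].father_id != father_id:
            raise PedigreeError(f"{father_id!r} is not the father of {did!r}")
    removals: dict[VariantKey, set] = {}
    for key in callset.variants():
        carriers = callset.carriers(key)
        if father_id not in carriers:
            continue
        shared = carriers & set(daughters)
        if shared:
            removals[key] = set(shared)
    edited = callset.without_sample_presence(removals)
    # a variant that was father-daughter shared and now survives only in the
    # father carries no family signal: drop it entirely
    keep = [
        key
        for key in edited.variants()
        if not (key in removals and edited.carriers(key) <= {father_id})
    ]
    return edited.restrict(keep)


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def _father_daughter_groups(
    pedigree: Pedigree, samples: Iterable[str]
) -> list[tuple[str, tuple[str, ...]]]:
    sample_set = set(samples)
    groups = []
    for member in pedigree:
        if member.sex != "male" or member.id not in sample_set:
            continue
        daughters = tuple(
            d for d in pedigree.daughters_of(member.id) if d in sample_set
        )
        if daughters:
            groups.append((member.id, daughters))
    return sorted(groups)


def run_cascade(
    callset: CohortCallset,
    annotations: Mapping[VariantKey, VariantAnnotation],
    pedigree: Pedigree,
    config: FilterConfig,
    strict: bool = True,
) -> CascadeResult:
    """Compose the full prioritization cascade; deterministic.

    ``strict=True`` raises :class:`MissingAnnotationError` for a surviving
    variant without an annotation row; lenient mode drops it with a warning
    in the audit.  The confirmation stage only runs when
    ``config.require_confirmation`` is set, and drops variants whose
    ``sanger_confirmed`` flag is not True.
    """
    config.validate_against(pedigree)
    audit = CascadeAudit()

    merged = consensus_callers(callset, config.caller_mode)
    audit.record("caller_consensus", callset.variants(), merged.variants())

    current = remove_shared_with_unaffected(merged, pedigree, config.control_ids)
    audit.record("unaffected_subtraction", merged.variants(), current.variants())

    # annotation-backed restrictions operate on keys still in play
    def annotation_for(key: VariantKey) -> Optional[VariantAnnotation]:
        ann = annotations.get(key)
        if ann is None:
            if strict:
                raise MissingAnnotationError(f"no annotation for {key}")
            audit.warnings.append(f"dropping unannotated variant {key}")
        return ann

    live = {k: annotation_for(k) for k in current.variants()}
    live = {k: a for k, a in live.items() if a is not None}
    if len(live) < len(current.variants()):
        dropped = current.restrict(live)
        audit.record("annotation_join", current.variants(), dropped.variants())
        current = dropped

    rare = filter_rare(live, config.maf_threshold)
    after = current.restrict(rare)
    audit.record("maf_filter", current.variants(), after.variants())
    current, live = after, rare

    classed = filter_functional_class(live, config.kept_classes)
    after = current.restrict(classed)
    audit.record("functional_class_filter", current.variants(), after.variants())
    current, live = after, classed

    deleterious = {
        k: a for k, a in live.items() if predict_deleterious(a, config, audit)
    }
    after = current.restrict(deleterious)
    audit.record("deleteriousness_filter", current.variants(), after.variants())
    current, live = after, deleterious

    before_keys = current.variants()
    for father_id, daughters in _father_daughter_groups(pedigree, callset.samples):
        current = remove_paternal(current, pedigree, father_id, daughters)
    audit.record("paternal_removal", before_keys, current.variants())

    if config.require_confirmation:
        confirmed = [
            k for k in current.variants() if annotations[k].sanger_confirmed is True
        ]
        after = current.restrict(confirmed)
        audit.record("confirmation_filter", current.variants(), after.variants())
        current = after

    return CascadeResult(callset=current, audit=audit)
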
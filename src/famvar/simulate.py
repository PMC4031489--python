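"""Synthetic two-generation family variant data with known truth.

Three variant populations are spiked into a pedigree:

* rare deleterious *founder* variants, heterozygous in one designated
  founder and transmitted Mendelian-style down the lineage;
* *de novo* variants, each unique to a single individual (never
  transmitted: they model post-zygotic blood-cell mutations);
* a *common polymorphism background*, Hardy-Weinberg sampled in all
  pedigree founders from configured catalog MAFs, with tolerant scores.

Annotation scores are spiked so truth-deleterious variants satisfy the
SIFT/PolyPhen OR rule and background variants fail the MAF filter, making
simulation truth a usable oracle for the whole cascade.  The same seed
produces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pysam

from famvar.core.io import _vcf_header, _chrom_sort_key, write_annotation_table, write_pedigree
from famvar.core.types import (
    CohortCallset,
    FunctionalClass,
    Individual,
    Pedigree,
    VariantAnnotation,
    VariantKey,
)
from famvar.errors import ConfigError, InputError
from famvar.inheritance import DE_NOVO, GERMLINE, InheritanceRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "TruthVariant",
    "SimResult",
    "default_family_pedigree",
    "mendelian_transmit",
    "simulate_family",
    "recovery_report",
    "RecoveryReport",
    "expected_final_keys",
]

FOUNDER_GERMLINE = "founder_germline"
COMMON_BACKGROUND = "common_background"


def default_family_pedigree() -> Pedigree:
    """Two-generation family: four sisters (three affected), two marry-in
    fathers, three affected daughters, one unaffected son.  The sisters'
    parents ("gm"/"gf") are unsequenced founders; "gm" carries the founder
    lineage."""
    f, m = "female", "male"
    return Pedigree(
        [
            Individual("gm", f, carrier=True),
            Individual("gf", m),
            Individual("1", f, father_id="gf", mother_id="gm", affected=True, carrier=True),
            Individual("2", f, father_id="gf", mother_id="gm", affected=True, carrier=True),
            Individual("3", f, father_id="gf", mother_id="gm", affected=False),
            Individual("4", f, father_id="gf", mother_id="gm", affected=True, carrier=True),
            Individual("9", m),
            Individual("10", m),
            Individual("5", f, father_id="9", mother_id="2", affected=True, carrier=True),
            Individual("6", f, father_id="9", mother_id="2", affected=True, carrier=True),
            Individual("7", f, father_id="10", mother_id="4", affected=True, carrier=True),
            Individual("8", m, father_id="10", mother_id="4", affected=False),
        ]
    )


@dataclass
class SimConfig:
    """Simulation parameters; ``seed`` fully determines all output."""

    seed: int = 0
    pedigree: Optional[Pedigree] = None
    sequenced: Optional[tuple[str, ...]] = None  # default: all but gm/gf
    founder_carrier_id: str = "gm"
    n_founder_rare_deleterious: int = 10
    denovo_mean: Union[float, Mapping[str, float]] = 1.0
    n_common_background: int = 50
    background_maf_range: tuple[float, float] = (0.01, 0.5)
    transmission_prob: float = 0.5
    dropout_rate: float = 0.0
    callers: tuple[str, ...] = ("callerA", "callerB")
    stopgain_fraction: float = 0.1  # of spiked deleterious variants
    chromosomes: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

    def __post_init__(self) -> None:
        for name in ("transmission_prob", "dropout_rate", "stopgain_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {value}")
        lo, hi = self.background_maf_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("background_maf_range must satisfy 0 <= lo <= hi <= 1")
        if self.pedigree is None:
            self.pedigree = default_family_pedigree()
        if self.founder_carrier_id not in self.pedigree:
            raise ConfigError(f"founder {self.founder_carrier_id!r} not in pedigree")
        if self.sequenced is None:
            self.sequenced = tuple(
                m.id for m in self.pedigree if m.id not in ("gm", "gf")
            )
        for sid in self.sequenced:
            if sid not in self.pedigree:
                raise ConfigError(f"sequenced sample {sid!r} not in pedigree")

    def denovo_mean_for(self, individual_id: str) -> float:
        if isinstance(self.denovo_mean, Mapping):
            return float(self.denovo_mean.get(individual_id, 0.0))
        return float(self.denovo_mean)


@dataclass(frozen=True)
class TruthVariant:
    origin: str  # FOUNDER_GERMLINE | DE_NOVO | COMMON_BACKGROUND
    origin_individual: Optional[str]  # set for de novo variants
    carriers: frozenset  # sequenced carriers
    deleterious: bool
    maf: Optional[float] = None


@dataclass
class SimTruth:
    variants: dict[VariantKey, TruthVariant] = field(default_factory=dict)

    def positives(self, affected: Iterable[str], controls: Iterable[str]) -> set[VariantKey]:
        """Spiked rare deleterious variants present in >= 1 affected member
        and in no control: the set the cascade should recover exactly."""
        affected_set, control_set = set(affected), set(controls)
        return {
            key
            for key, tv in self.variants.items()
            if tv.origin != COMMON_BACKGROUND
            and tv.deleterious
            and tv.carriers & affected_set
            and not (tv.carriers & control_set)
        }


@dataclass
class SimResult:
    config: SimConfig
    callset: CohortCallset
    annotations: dict[VariantKey, VariantAnnotation]
    pedigree: Pedigree
    truth: SimTruth
    paths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# transmission
# ---------------------------------------------------------------------------

def mendelian_transmit(
    mother_carrier: bool,
    father_carrier: bool,
    rng: np.random.Generator,
    transmission_prob: float = 0.5,
) -> bool:
    """Child carries a parental heterozygous variant when any carrying
    parent transmits it, independently with ``transmission_prob``."""
    got = False
    if mother_carrier:
        got |= rng.random() < transmission_prob
    if father_carrier:
        got |= rng.random() < transmission_prob
    return got


def _transmit_allele(parent_count: int, rng: np.random.Generator, p_het: float) -> int:
    """One allele from a parent with the given alt-allele count (0/1/2)."""
    if parent_count == 0:
        return 0
    if parent_count == 2:
        return 1
    return int(rng.random() < p_het)


# ---------------------------------------------------------------------------
# variant placement and annotation spiking
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _draw_keys(n: int, rng: np.random.Generator, chromosomes, used: set) -> list[VariantKey]:
    keys: list[VariantKey] = []
    while len(keys) < n:
        chrom = str(rng.choice(np.array(chromosomes)))
        pos = int(rng.integers(1, 100_000_000))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice(_BASES[_BASES != ref]))
        key = VariantKey(chrom, pos, ref, alt)
        if (key.chrom, key.pos) in used:
            continue
        used.add((key.chrom, key.pos))
        keys.append(key)
    return keys


def _spiked_annotation(
    key: VariantKey, gene: str, rng: np.random.Generator, config: SimConfig
) -> VariantAnnotation:
    """Annotation guaranteed to pass class + MAF + deleteriousness filters."""
    if rng.random() < config.stopgain_fraction:
        return VariantAnnotation(
            key=key, gene=gene, functional_class=FunctionalClass.stopgain,
            sanger_confirmed=True,
        )
    pattern = rng.integers(0, 3)  # damaging by SIFT, by PolyPhen, or both
    sift = float(rng.uniform(0.0, 0.049)) if pattern in (0, 2) else float(rng.uniform(0.1, 1.0))
    polyphen = float(rng.uniform(0.5, 1.0)) if pattern in (1, 2) else float(rng.uniform(0.0, 0.4))
    return VariantAnnotation(
        key=key, gene=gene, functional_class=FunctionalClass.nonsynonymous_SNV,
        sift=round(sift, 3), polyphen_hvar=round(polyphen, 3), sanger_confirmed=True,
    )


def _background_annotation(
    key: VariantKey, gene: str, maf: float, rng: np.random.Generator
) -> VariantAnnotation:
    cls = FunctionalClass.synonymous if rng.random() < 0.5 else FunctionalClass.nonsynonymous_SNV
    return VariantAnnotation(
        key=key, gene=gene, functional_class=cls,
        maf={"1000G": round(maf, 4)},
        sift=round(float(rng.uniform(0.3, 1.0)), 3),
        polyphen_hvar=round(float(rng.uniform(0.0, 0.4)), 3),
    )


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def simulate_family(config: SimConfig, out_dir: Optional[Union[str, Path]] = None) -> SimResult:
    """Simulate the family; optionally write VCF/PED/TSV/JSON under *out_dir*."""
    rng = np.random.default_rng(config.seed)
    pedigree = config.pedigree
    assert pedigree is not None and config.sequenced is not None
    sequenced = tuple(config.sequenced)
    order = pedigree.topological_order()
    used_positions: set = set()

    truth = SimTruth()
    annotations: dict[VariantKey, VariantAnnotation] = {}
    counts: dict[VariantKey, dict[str, int]] = {}  # allele counts per member

    # --- founder rare deleterious variants (het chain from one founder) ---
    founder_keys = _draw_keys(
        config.n_founder_rare_deleterious, rng, config.chromosomes, used_positions
    )
    for i, key in enumerate(founder_keys):
        carrier = {config.founder_carrier_id: 1}
        for mid in order:
            member = pedigree[mid]
            if mid in carrier or (member.father_id is None and member.mother_id is None):
                continue
            inherited = mendelian_transmit(
                bool(carrier.get(member.mother_id or "", 0)),
                bool(carrier.get(member.father_id or "", 0)),
                rng,
                config.transmission_prob,
            )
            if inherited:
                carrier[mid] = 1
        counts[key] = carrier
        truth.variants[key] = TruthVariant(
            origin=FOUNDER_GERMLINE,
            origin_individual=None,
            carriers=frozenset(s for s in sequenced if carrier.get(s, 0)),
            deleterious=True,
        )
        annotations[key] = _spiked_annotation(key, f"FGENE{i + 1}", rng, config)

    # --- de novo variants, unique to one individual, never transmitted ---
    denovo_serial = 0
    for sid in sequenced:
        n = int(rng.poisson(config.denovo_mean_for(sid)))
        for key in _draw_keys(n, rng, config.chromosomes, used_positions):
            denovo_serial += 1
            counts[key] = {sid: 1}
            truth.variants[key] = TruthVariant(
                origin=DE_NOVO,
                origin_individual=sid,
                carriers=frozenset({sid}),
                deleterious=True,
            )
            annotations[key] = _spiked_annotation(key, f"DGENE{denovo_serial}", rng, config)

    # --- common polymorphism background, Hardy-Weinberg in founders ---
    lo, hi = config.background_maf_range
    background_keys = _draw_keys(
        config.n_common_background, rng, config.chromosomes, used_positions
    )
    for i, key in enumerate(background_keys):
        maf = float(rng.uniform(lo, hi))
        allele: dict[str, int] = {}
        for mid in order:
            member = pedigree[mid]
            if member.father_id is None and member.mother_id is None:
                allele[mid] = int(rng.binomial(2, maf))
            else:
                allele[mid] = _transmit_allele(
                    allele.get(member.mother_id or "", 0), rng, config.transmission_prob
                ) + _transmit_allele(
                    allele.get(member.father_id or "", 0), rng, config.transmission_prob
                )
        counts[key] = {m: c for m, c in allele.items() if c}
        truth.variants[key] = TruthVariant(
            origin=COMMON_BACKGROUND,
            origin_individual=None,
            carriers=frozenset(s for s in sequenced if allele.get(s, 0)),
            deleterious=False,
            maf=maf,
        )
        annotations[key] = _background_annotation(key, f"BGENE{i + 1}", maf, rng)

    # --- per-caller presence with independent dropout -------------------
    per_caller: dict[str, dict[VariantKey, frozenset]] = {c: {} for c in config.callers}
    for key in sorted(counts):
        carrier_counts = counts[key]
        for caller in config.callers:
            observed = [
                s
                for s in sequenced
                if carrier_counts.get(s, 0) > 0
                and (config.dropout_rate == 0.0 or rng.random() >= config.dropout_rate)
            ]
            if observed:
                per_caller[caller][key] = frozenset(observed)
    callset = CohortCallset(sequenced, per_caller=per_caller)

    result = SimResult(
        config=config,
        callset=callset,
        annotations=annotations,
        pedigree=pedigree,
        truth=truth,
    )
    if out_dir is not None:
        result.paths = _write_outputs(result, Path(out_dir), counts)
    return result


def _write_outputs(result: SimResult, out_dir: Path, counts) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"vcf": {}}
    samples = result.callset.samples
    for caller in result.callset.callers:
        matrix = result.callset.per_caller[caller]
        path = out_dir / f"{caller}.vcf"
        keys = sorted(matrix, key=lambda k: (_chrom_sort_key(k.chrom), k.pos, k.ref, k.alt))
        chroms = sorted({k.chrom for k in keys}, key=_chrom_sort_key)
        header = _vcf_header(samples, chroms)
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for key in keys:
                record = vf.new_record(
                    contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
                )
                for s in samples:
                    if s in matrix[key]:
                        gt = (1, 1) if counts[key].get(s, 0) >= 2 else (0, 1)
                    else:
                        gt = (0, 0)
                    record.samples[s]["GT"] = gt
                vf.write(record)
        paths["vcf"][caller] = path

    paths["ped"] = out_dir / "family.ped"
    write_pedigree(result.pedigree, paths["ped"])
    paths["annotations"] = out_dir / "annotations.tsv"
    write_annotation_table(result.annotations, paths["annotations"])
    paths["truth"] = out_dir / "truth.json"
    with open(paths["truth"], "w") as handle:
        json.dump(
            {
                str(key): {
                    "origin": tv.origin,
                    "origin_individual": tv.origin_individual,
                    "carriers": sorted(tv.carriers),
                    "deleterious": tv.deleterious,
                    "maf": tv.maf,
                }
                for key, tv in sorted(result.truth.variants.items())
            },
            handle,
            indent=1,
            sort_keys=True,
        )
        handle.write("\n")
    return paths


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def expected_final_keys(
    truth: SimTruth, pedigree: Pedigree, control_ids: Iterable[str]
) -> set[VariantKey]:
    return truth.positives(pedigree.affected_ids, control_ids)


@dataclass
class RecoveryReport:
    tp: int
    fp: int
    fn: int
    tn: int
    false_positive_keys: tuple[VariantKey, ...]
    false_negative_keys: tuple[VariantKey, ...]
    label_mismatches: tuple[tuple[VariantKey, str, str, str], ...]  # (key, daughter, got, want)

    @property
    def discordant(self) -> int:
        return self.fp + self.fn + len(self.label_mismatches)


def recovery_report(
    final_keys: Iterable[VariantKey],
    truth: SimTruth,
    pedigree: Pedigree,
    control_ids: Iterable[str] = (),
    records: Optional[Iterable[InheritanceRecord]] = None,
) -> RecoveryReport:
    """Confusion counts for final-set membership and inheritance labels.

    The variant universe is the simulation truth; pipeline keys outside it
    raise :class:`InputError`.
    """
    final = set(final_keys)
    universe = set(truth.variants)
    foreign = final - universe
    if foreign:
        raise InputError(f"pipeline output contains non-simulated variants {sorted(foreign)[:3]}")
    expected = expected_final_keys(truth, pedigree, control_ids)
    tp = len(final & expected)
    fp_keys = tuple(sorted(final - expected))
    fn_keys = tuple(sorted(expected - final))
    tn = len(universe - expected - final)

    mismatches: list[tuple[VariantKey, str, str, str]] = []
    if records is not None:
        for record in records:
            tv = truth.variants.get(record.key)
            if tv is None:
                raise InputError(f"inheritance record for non-simulated variant {record.key}")
            mother = pedigree[record.daughter_id].mother_id
            want = GERMLINE if (mother is not None and mother in tv.carriers) else DE_NOVO
            if record.label != want:
                mismatches.append((record.key, record.daughter_id, record.label, want))
    return RecoveryReport(
        tp=tp,
        fp=len(fp_keys),
        fn=len(fn_keys),
        tn=tn,
        false_positive_keys=fp_keys,
        false_negative_keys=fn_keys,
        label_mismatches=tuple(mismatches),
    )
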
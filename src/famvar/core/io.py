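"""Readers/writers for VCF, PED, BED and the annotation table.

Coordinate conventions at the boundary:

* VCF positions are already 1-based and pass through unchanged.
* BED is 0-based half-open on disk and converted to the internal 1-based
  closed convention on read (``start+1, end``), and back on write.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, TextIO, Union

import pandas as pd
import pysam

from famvar.core.types import (
    CohortCallset,
    FunctionalClass,
    Individual,
    Interval,
    IntervalTrack,
    Pedigree,
    VariantAnnotation,
    VariantKey,
    normalize_key,
)
from famvar.errors import (
    DuplicateKeyError,
    FormatError,
    InvalidAlleleError,
    RangeError,
)

PathLike = Union[str, Path]
_MISSING = {"", ".", "na", "nan", "none", "-9"}


def _lines(source: Union[PathLike, TextIO, Iterable[str]]) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            yield from handle
    else:
        yield from source


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def parse_pedigree(source: Union[PathLike, TextIO, Iterable[str]]) -> Pedigree:
    """Parse a 6+ column PED file into a :class:`Pedigree`.

    Columns: family, individual, father, mother, sex (1=male, 2=female),
    phenotype (2=affected).  An optional 7th column carries carrier status
    (1=carrier, 0=non-carrier) and an optional 8th column age in years.
    Parent id ``0`` marks a founder.
    """
    members: list[Individual] = []
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"PED line {lineno}: expected >= 6 columns, got {len(fields)}")
        _fam, iid, father, mother, sex_code, pheno = fields[:6]
        carrier: Optional[bool] = None
        if len(fields) >= 7 and fields[6].lower() not in _MISSING:
            carrier = fields[6] in ("1", "yes", "true", "Y")
        age: Optional[float] = None
        if len(fields) >= 8 and fields[7].lower() not in _MISSING:
            try:
                age = float(fields[7])
            except ValueError:
                raise FormatError(f"PED line {lineno}: bad age {fields[7]!r}") from None
        members.append(
            Individual(
                id=iid,
                sex={"1": "male", "2": "female"}.get(sex_code, "unknown"),
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                affected=pheno == "2",
                carrier=carrier,
                age=age,
            )
        )
    return Pedigree(members)


def write_pedigree(
    pedigree: Pedigree, target: Union[PathLike, TextIO], family_id: str = "FAM"
) -> None:
    """Write a pedigree back out in the PED dialect accepted by :func:`parse_pedigree`."""
    own = isinstance(target, (str, Path))
    handle = open(target, "w") if own else target
    try:
        for m in pedigree:
            sex = {"male": "1", "female": "2"}.get(m.sex, "0")
            pheno = "2" if m.affected else "1"
            cols = [
                family_id,
                m.id,
                m.father_id or "0",
                m.mother_id or "0",
                sex,
                pheno,
            ]
            if m.carrier is not None or m.age is not None:
                cols.append("-9" if m.carrier is None else ("1" if m.carrier else "0"))
            if m.age is not None:
                cols.append(f"{m.age:g}")
            handle.write("\t".join(cols) + "\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _alt_presence(record, alt_index: int) -> frozenset:
    carriers = []
    for sample, call in record.samples.items():
        gt = call.get("GT")
        if gt is None or all(a is None for a in gt):
            continue
        if alt_index in gt:
            carriers.append(sample)
    return frozenset(carriers)


def read_cohort_vcf(
    sources: Mapping,
    samples: Optional[Iterable[str]] = None,
) -> CohortCallset:
    """Read per-caller VCFs into a :class:`CohortCallset`.

    ``sources`` maps either ``caller -> path`` (multi-sample VCF per caller)
    or ``(sample, caller) -> path`` (single-sample VCFs).  Presence of a
    variant means the sample carries at least one copy of that alt allele;
    multi-allelic records are split into one key per alt.  Records whose
    genotype field is entirely missing are skipped and counted in
    ``callset.meta["skipped_missing_gt"]``; alt alleles that are not plain
    sequence (symbolic, ``*``) are skipped and counted in
    ``callset.meta["skipped_non_sequence_alt"]``.
    """
    per_caller: dict[str, dict[VariantKey, set]] = {}
    seen_samples: list[str] = []
    skipped_gt = 0
    skipped_alt = 0

    def note_sample(s: str) -> None:
        if s not in seen_samples:
            seen_samples.append(s)

    def scan(path: PathLike, caller: str, only_sample: Optional[str] = None) -> None:
        nonlocal skipped_gt, skipped_alt
        matrix = per_caller.setdefault(caller, {})
        try:
            vf = pysam.VariantFile(str(path))
        except (ValueError, OSError) as exc:
            raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
        with vf:
            for s in vf.header.samples:
                if only_sample is None or s == only_sample:
                    note_sample(s)
            for record in vf:
                if not record.alts:
                    continue
                any_gt = any(
                    record.samples[s].get("GT") is not None
                    and not all(a is None for a in record.samples[s].get("GT"))
                    for s in record.samples
                )
                if not any_gt:
                    skipped_gt += 1
                    continue
                for i, alt in enumerate(record.alts, start=1):
                    try:
                        key = normalize_key(record.chrom, record.pos, record.ref, alt)
                    except InvalidAlleleError:
                        skipped_alt += 1
                        continue
                    carriers = _alt_presence(record, i)
                    if only_sample is not None:
                        carriers = carriers & {only_sample}
                    if carriers:
                        matrix.setdefault(key, set()).update(carriers)

    for key, path in sources.items():
        if isinstance(key, tuple):
            sample, caller = key
            scan(path, caller, only_sample=sample)
        else:
            scan(path, str(key))

    ordered = list(samples) if samples is not None else seen_samples
    return CohortCallset(
        ordered,
        per_caller={c: {k: frozenset(v) for k, v in m.items()} for c, m in per_caller.items()},
        meta={
            "skipped_missing_gt": skipped_gt,
            "skipped_non_sequence_alt": skipped_alt,
        },
    )


def _vcf_header(samples: Iterable[str], chroms: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in chroms:
        header.add_line(f"##contig=<ID={chrom}>")
    for s in samples:
        header.add_sample(s)
    return header


def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def write_cohort_vcf(
    callset: CohortCallset,
    directory: PathLike,
    genotype: str = "het",
) -> dict:
    """Write the callset as uncompressed VCF, one file per caller.

    A merged callset is written as a single ``cohort.vcf``.  Presence is
    emitted as genotype ``0/1`` (``genotype="het"``); absent samples get
    ``0/0``.  Returns a mapping of caller name (or ``"merged"``) to path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrices: dict[str, Mapping[VariantKey, frozenset]] = {}
    if callset.per_caller:
        matrices.update(callset.per_caller)
    elif callset.is_merged:
        matrices["merged"] = callset.merged or {}
    paths = {}
    gt = (0, 1) if genotype == "het" else (1, 1)
    for name, matrix in matrices.items():
        filename = "cohort.vcf" if name == "merged" else f"{name}.vcf"
        path = directory / filename
        keys = sorted(matrix, key=lambda k: (_chrom_sort_key(k.chrom), k.pos, k.ref, k.alt))
        chroms = sorted({k.chrom for k in keys}, key=_chrom_sort_key)
        header = _vcf_header(callset.samples, chroms)
        with pysam.VariantFile(str(path), "w", header=header) as vf:
            for key in keys:
                record = vf.new_record(
                    contig=key.chrom,
                    start=key.pos - 1,
                    alleles=(key.ref, key.alt),
                )
                carriers = matrix[key]
                for s in callset.samples:
                    record.samples[s]["GT"] = gt if s in carriers else (0, 0)
                vf.write(record)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# BED interval tracks
# ---------------------------------------------------------------------------

def read_interval_track(
    source: Union[PathLike, TextIO, Iterable[str]], name: str
) -> IntervalTrack:
    """Read a BED (0-based half-open) stream into a 1-based closed track."""
    intervals: list[Interval] = []
    for lineno, raw in enumerate(_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise FormatError(f"BED line {lineno}: expected >= 3 columns")
        chrom = fields[0]
        try:
            start0, end0 = int(fields[1]), int(fields[2])
        except ValueError:
            raise FormatError(f"BED line {lineno}: non-integer coordinates") from None
        if start0 > end0 or start0 < 0:
            raise FormatError(
                f"BED line {lineno}: bad interval [{start0}, {end0})"
            )
        if start0 == end0:
            continue  # zero-length BED feature covers no base
        label = fields[3] if len(fields) >= 4 else ""
        intervals.append(Interval(chrom=chrom, start=start0 + 1, end=end0, label=label))
    return IntervalTrack(name=name, intervals=intervals)


def write_interval_track(track: IntervalTrack, target: Union[PathLike, TextIO]) -> None:
    """Write a track back to BED (converting to 0-based half-open)."""
    own = isinstance(target, (str, Path))
    handle = open(target, "w") if own else target
    try:
        for iv in track:
            cols = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if iv.label:
                cols.append(iv.label)
            handle.write("\t".join(cols) + "\n")
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

#: fixed columns of the annotation TSV; catalog MAFs use ``maf_<catalog>``.
_ANN_REQUIRED = ("chrom", "pos", "ref", "alt", "gene", "functional_class")
_ANN_OPTIONAL = (
    "cdna_change",
    "protein_change",
    "known_id",
    "sift",
    "polyphen_hvar",
    "sanger_confirmed",
)


def _cell(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    return None if text.lower() in _MISSING else text


def read_annotation_table(
    source: Union[PathLike, TextIO],
) -> dict[VariantKey, VariantAnnotation]:
    """Read the tab-separated annotation table keyed by :class:`VariantKey`.

    Score and MAF cells left empty (or ``NA``/``.``) parse as *absent*,
    never as zero.  Catalog MAF columns are named ``maf_<catalog>``.
    """
    if isinstance(source, (str, Path)):
        frame = pd.read_csv(source, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(_io.StringIO(source.read()), sep="\t", dtype=str)
    missing = [c for c in _ANN_REQUIRED if c not in frame.columns]
    if missing:
        raise FormatError(f"annotation table missing columns {missing}")
    maf_columns = [c for c in frame.columns if c.startswith("maf_")]

    annotations: dict[VariantKey, VariantAnnotation] = {}
    for row in frame.itertuples(index=False):
        record = row._asdict()
        key = normalize_key(
            record["chrom"], int(record["pos"]), record["ref"], record["alt"]
        )
        if key in annotations:
            raise DuplicateKeyError(f"duplicate annotation row for {key}")
        maf: dict[str, float] = {}
        for column in maf_columns:
            cell = _cell(record.get(column))
            if cell is None:
                continue
            value = float(cell)
            if not (0.0 <= value <= 1.0):
                raise RangeError(f"MAF {value} in column {column} outside [0,1]")
            maf[column[len("maf_"):]] = value

        def score(column: str) -> Optional[float]:
            cell = _cell(record.get(column))
            if cell is None:
                return None
            value = float(cell)
            if not (0.0 <= value <= 1.0):
                raise RangeError(f"{column} score {value} outside [0,1]")
            return value

        confirmed_cell = _cell(record.get("sanger_confirmed"))
        annotations[key] = VariantAnnotation(
            key=key,
            gene=_cell(record.get("gene")) or "",
            cdna_change=_cell(record.get("cdna_change")) or "",
            protein_change=_cell(record.get("protein_change")) or "",
            functional_class=FunctionalClass.parse(record["functional_class"]),
            known_id=_cell(record.get("known_id")),
            maf=maf,
            sift=score("sift"),
            polyphen_hvar=score("polyphen_hvar"),
            sanger_confirmed=(
                None
                if confirmed_cell is None
                else confirmed_cell.lower() in ("1", "true", "yes", "y")
            ),
        )
    return annotations


def write_annotation_table(
    annotations: Mapping[VariantKey, VariantAnnotation],
    target: Union[PathLike, TextIO],
) -> None:
    """Write annotations as the TSV dialect read by :func:`read_annotation_table`."""
    catalogs = sorted({c for a in annotations.values() for c in a.maf})
    columns = list(_ANN_REQUIRED) + list(_ANN_OPTIONAL) + [f"maf_{c}" for c in catalogs]
    rows = []
    for key in sorted(annotations):
        a = annotations[key]
        row = {
            "chrom": key.chrom,
            "pos": key.pos,
            "ref": key.ref,
            "alt": key.alt,
            "gene": a.gene,
            "functional_class": a.functional_class.value,
            "cdna_change": a.cdna_change or "",
            "protein_change": a.protein_change or "",
            "known_id": a.known_id or "",
            "sift": "" if a.sift is None else f"{a.sift:g}",
            "polyphen_hvar": "" if a.polyphen_hvar is None else f"{a.polyphen_hvar:g}",
            "sanger_confirmed": (
                "" if a.sanger_confirmed is None else str(a.sanger_confirmed).lower()
            ),
        }
        for c in catalogs:
            row[f"maf_{c}"] = "" if c not in a.maf else f"{a.maf[c]:g}"
        rows.append(row)
    frame = pd.DataFrame(rows, columns=columns)
    if isinstance(target, (str, Path)):
        frame.to_csv(target, sep="\t", index=False)
    else:
        target.write(frame.to_csv(sep="\t", index=False))
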
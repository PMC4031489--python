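"""Bundled study fixtures: a two-generation breast-cancer family.

The data files under ``data/`` encode the published summary tables of a
family exome study (eight sequenced members plus two fathers used for
paternal subtraction): the 23-variant prioritized mutation table with
scores and affected-carrier frequencies, the sister and mother-daughter
presence matrices, and the fragile-site intervals.  Callsets ship as
plain-text per-caller VCFs plus small presence-matrix TSVs.

Note the published subtraction used only the unaffected sister ("3") as a
control: one prioritized variant is also carried by the unaffected son
("8"), so the study configuration returned by :func:`study_filter_config`
sets ``control_ids=("3",)``.
"""

from __future__ import annotations

from importlib.resources import as_file, files
from pathlib import Path
from typing import Iterable, TextIO, Union

import pandas as pd

from famvar.core.io import (
    parse_pedigree,
    read_annotation_table,
    read_cohort_vcf,
    read_interval_track,
)
from famvar.core.types import (
    CohortCallset,
    FilterConfig,
    IntervalTrack,
    Pedigree,
    VariantAnnotation,
    VariantKey,
    normalize_key,
)
from famvar.errors import FormatError

__all__ = [
    "data_path",
    "load_pedigree",
    "load_annotations",
    "load_caller_vcfs",
    "load_cohort",
    "load_sister_callset",
    "load_pair_callsets",
    "load_fragile_sites",
    "study_filter_config",
    "read_presence_matrix",
    "SISTER_IDS",
]

#: the three affected sisters of the founder generation
SISTER_IDS = ("1", "2", "4")

_FIXED_COLUMNS = ("chrom", "pos", "ref", "alt", "gene")


def data_path(name: str) -> Path:
    resource = files(__package__) / "data" / name
    with as_file(resource) as path:
        return Path(path)


def load_pedigree() -> Pedigree:
    return parse_pedigree(data_path("family.ped"))


def load_annotations() -> dict[VariantKey, VariantAnnotation]:
    return read_annotation_table(data_path("variants.tsv"))


def load_caller_vcfs() -> dict[str, Path]:
    return {
        "varscan": data_path("varscan.vcf"),
        "gatk": data_path("gatk.vcf"),
    }


def load_cohort() -> CohortCallset:
    """Full cohort callset (samples 1-10) read from the per-caller VCFs."""
    pedigree = load_pedigree()
    return read_cohort_vcf(load_caller_vcfs(), samples=pedigree.ids)


def read_presence_matrix(
    source: Union[str, Path, TextIO], samples: Iterable[str] | None = None
) -> CohortCallset:
    """Read a ``+/-`` presence matrix TSV into a merged callset.

    Columns ``chrom, pos, ref, alt, gene`` are fixed; every further column
    is a sample id whose cells are ``+`` (present) or ``-`` (absent).
    """
    frame = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in _FIXED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"presence matrix missing columns {missing}")
    sample_columns = [c for c in frame.columns if c not in _FIXED_COLUMNS]
    carriers: dict[VariantKey, set] = {}
    for record in frame.to_dict("records"):
        key = normalize_key(record["chrom"], int(record["pos"]), record["ref"], record["alt"])
        cell_carriers = set()
        for sample in sample_columns:
            cell = str(record[sample]).strip()
            if cell == "+":
                cell_carriers.add(sample)
            elif cell != "-":
                raise FormatError(f"presence cell must be '+' or '-', got {cell!r}")
        carriers[key] = cell_carriers
    ordered = list(samples) if samples is not None else sample_columns
    return CohortCallset.from_merged(ordered, carriers)


def load_sister_callset() -> CohortCallset:
    """Presence matrix over the three affected sisters plus the unaffected
    sister ("3")."""
    return read_presence_matrix(data_path("sister_matrix.tsv"))


def load_pair_callsets() -> dict[str, dict]:
    """Mother-daughter pair presence matrices, paternal subtraction already
    reflected (father columns are all absent)."""
    return {
        "pair1": {
            "callset": read_presence_matrix(data_path("pair1_matrix.tsv")),
            "father": "9",
            "mother": "2",
            "daughters": ("5", "6"),
        },
        "pair2": {
            "callset": read_presence_matrix(data_path("pair2_matrix.tsv")),
            "father": "10",
            "mother": "4",
            "daughters": ("7",),
        },
    }


def load_fragile_sites() -> IntervalTrack:
    return read_interval_track(data_path("fragile_sites.bed"), name="fragile_sites")


def study_filter_config() -> FilterConfig:
    """Cascade configuration matching the published analysis."""
    return FilterConfig(
        control_ids=("3",),
        caller_mode="intersection",
        require_confirmation=True,
        provenance={"min_read_depth": 10, "min_base_quality": 30},
    )
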
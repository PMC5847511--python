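"""Variant cohort handling: read, merge, deduplicate, somatic-only subset.

A variant's identity is the substitution itself — (accession, position,
ref, alt) — never its provenance: the somatic-versus-germline overlap
must be computed on the substitution, so records with the same key from
different databases are collapsed with their sources and disease
annotations unioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .engine import VariantRecord
from .proteome import ProteomeSet

logger = logging.getLogger(__name__)

COHORT_LABELS = frozenset({"somatic", "germline", "somatic_only"})

VariantKey = tuple[str, int, str, str]


class CohortError(ValueError):
    pass


@dataclass
class VariantCohort:
    """A deduplicated set of variants sharing one origin label."""

    variants: list[VariantRecord]
    origin_label: str

    def __post_init__(self) -> None:
        if self.origin_label not in COHORT_LABELS:
            raise CohortError(f"unknown origin label {self.origin_label!r}")
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise CohortError("duplicate variant keys in cohort")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def keys(self) -> set[VariantKey]:
        return {v.key for v in self.variants}


@dataclass
class RejectionReport:
    """Counts of variants rejected while validating against a proteome."""

    n_valid: int = 0
    n_unknown_accession: int = 0
    n_out_of_range: int = 0
    n_ref_mismatch: int = 0
    n_malformed: int = 0
    malformed_lines: list[int] = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {
            "valid": self.n_valid,
            "unknown_accession": self.n_unknown_accession,
            "out_of_range": self.n_out_of_range,
            "ref_mismatch": self.n_ref_mismatch,
            "malformed": self.n_malformed,
        }


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read a variant TSV.

    Header: ``accession  position  ref  alt  origin  source  doids``
    (doids semicolon-separated, may be empty).  Malformed rows are
    rejected with their line numbers logged.
    """
    out: list[VariantRecord] = []
    bad_lines: list[int] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["accession", "position", "ref", "alt", "origin", "source", "doids"]
        if header != expected:
            raise CohortError(f"variant header {header} != {expected}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                bad_lines.append(lineno)
                continue
            accession, pos_s, ref, alt, origin, source, doids = parts
            try:
                out.append(
                    VariantRecord(
                        accession=accession,
                        position=int(pos_s),
                        ref_aa=ref,
                        alt_aa=alt,
                        origin=origin,
                        sources=frozenset(s for s in source.split(";") if s),
                        doids=frozenset(d for d in doids.split(";") if d),
                    )
                )
            except ValueError:
                bad_lines.append(lineno)
    if bad_lines:
        logger.warning(
            "rejected %d malformed variant row(s) at line(s) %s",
            len(bad_lines),
            bad_lines[:10],
        )
    return out


def merge_variants(
    cohorts: Sequence[Iterable[VariantRecord]], origin_label: str | None = None
) -> VariantCohort:
    """Merge variant lists, collapsing equal keys and unioning annotation.

    All inputs must share one origin.  The result is order-insensitive:
    any permutation of the inputs yields an identical cohort.
    """
    merged: dict[VariantKey, VariantRecord] = {}
    origins: set[str] = set()
    for cohort in cohorts:
        for v in cohort:
            origins.add(v.origin)
            prev = merged.get(v.key)
            if prev is None:
                merged[v.key] = v
            else:
                merged[v.key] = VariantRecord(
                    accession=v.accession,
                    position=v.position,
                    ref_aa=v.ref_aa,
                    alt_aa=v.alt_aa,
                    origin=v.origin,
                    sources=prev.sources | v.sources,
                    doids=prev.doids | v.doids,
                )
    if len(origins) > 1:
        raise CohortError(f"cannot merge mixed origins {sorted(origins)}")
    label = origin_label or (origins.pop() if origins else "somatic")
    return VariantCohort(
        variants=[merged[k] for k in sorted(merged)], origin_label=label
    )


def somatic_only(somatic: VariantCohort, germline: VariantCohort) -> VariantCohort:
    """Somatic variants whose substitution key never occurs in the germline set."""
    if somatic.origin_label not in ("somatic", "somatic_only"):
        raise CohortError("first argument must be a somatic cohort")
    if germline.origin_label != "germline":
        raise CohortError("second argument must be a germline cohort")
    germline_keys = germline.keys
    return VariantCohort(
        variants=[v for v in somatic if v.key not in germline_keys],
        origin_label="somatic_only",
    )


def validate_against_proteome(
    cohort: VariantCohort, proteome: ProteomeSet
) -> tuple[list[VariantRecord], RejectionReport]:
    """Partition a cohort into proteome-consistent records and rejections."""
    report = RejectionReport()
    valid: list[VariantRecord] = []
    for v in cohort:
        if v.accession not in proteome:
            report.n_unknown_accession += 1
            continue
        record = proteome[v.accession]
        if v.position > record.length:
            report.n_out_of_range += 1
            continue
        if record.residue(v.position) != v.ref_aa:
            report.n_ref_mismatch += 1
            continue
        valid.append(v)
    report.n_valid = len(valid)
    return valid, report


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tposition\tref\talt\torigin\tsource\tdoids\n")
        for v in sorted(variants, key=lambda v: v.key):
            fh.write(
                f"{v.accession}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\t"
                f"{v.origin}\t{';'.join(sorted(v.sources))}\t"
                f"{';'.join(sorted(v.doids))}\n"
            )
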
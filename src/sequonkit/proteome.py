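"""Proteome containers and flat-file readers.

A proteome is a set of protein records (sequence plus light annotation:
signal peptide, cellular-component keywords) together with a table of
known N-glycosylation sites drawn from curated databases.  Coordinates
are 1-based and intervals closed throughout, matching the convention of
protein variant notation (T183A means position 183).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import ALLOWED_AA

logger = logging.getLogger(__name__)

EVIDENCE_LEVELS = frozenset({"experimental", "curated", "predicted"})
SITE_SOURCES = frozenset(
    {"uniprot_ft", "hprd", "dbptm", "nextprot", "ncbi_cdd", "other"}
)


class ProteomeError(ValueError):
    """Malformed proteome input (duplicate accession, bad residue, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, sequence, and viability-relevant annotation."""

    accession: str
    sequence: str
    gene_symbol: str | None = None
    signal_peptide: tuple[int, int] | None = None
    keywords: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ProteomeError("accession must be non-empty")
        bad = set(self.sequence) - ALLOWED_AA
        if bad:
            raise ProteomeError(
                f"{self.accession}: illegal residue(s) {sorted(bad)} in sequence"
            )
        if self.signal_peptide is not None:
            start, end = self.signal_peptide
            if not (1 <= start <= end <= len(self.sequence)):
                raise ProteomeError(
                    f"{self.accession}: signal peptide [{start},{end}] outside "
                    f"[1,{len(self.sequence)}]"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """1-based residue access."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"{self.accession}: position {position} outside [1,{self.length}]"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class KnownSite:
    """A database-annotated N-glycosylation position.

    ``atypical`` is true when the local 3-residue window does not match
    NXS/T (X != P) — e.g. the NXC variant sites — and such sites are
    flagged but never classified.
    """

    accession: str
    position: int
    evidence: str
    source: str
    atypical: bool = False

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ProteomeError(f"unknown evidence level {self.evidence!r}")
        if self.source not in SITE_SOURCES:
            raise ProteomeError(f"unknown site source {self.source!r}")
        if self.position < 1:
            raise ProteomeError("site position must be >= 1")


@dataclass
class ProteomeSet:
    """A proteome plus its known glycosylation sites."""

    records: dict[str, ProteinRecord] = field(default_factory=dict)
    known_sites: list[KnownSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self.records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self.records[accession]

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self.records:
            raise ProteomeError(f"duplicate accession {record.accession!r}")
        self.records[record.accession] = record


def _clean_sequence(accession: str, raw: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        warnings.warn(
            f"{accession}: stripping terminal stop codon '*'", stacklevel=2
        )
        seq = seq[:-1]
    bad = set(seq) - ALLOWED_AA
    if bad:
        raise ProteomeError(
            f"{accession}: illegal character(s) {sorted(bad)} in sequence"
        )
    return seq


def read_proteome(
    fasta_path: str | Path, annotation_path: str | Path | None = None
) -> ProteomeSet:
    """Read a FASTA proteome, optionally merging a TSV annotation table.

    The annotation table is tab-separated with header
    ``accession  signal_start  signal_end  keywords`` (keywords
    semicolon-separated; empty signal fields mean no signal peptide).
    Records without an annotation row get an empty keyword set.
    Annotation rows for accessions absent from the FASTA are skipped with
    a logged count.
    """
    annotations: dict[str, tuple[tuple[int, int] | None, frozenset[str]]] = {}
    if annotation_path is not None:
        annotations = _read_annotations(annotation_path)

    proteome = ProteomeSet()
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        accession = rec.id.split("|")[1] if rec.id.count("|") >= 2 else rec.id
        if accession in seen:
            raise ProteomeError(f"duplicate accession {accession!r} in FASTA")
        seen.add(accession)
        signal, keywords = annotations.pop(accession, (None, frozenset()))
        proteome.add(
            ProteinRecord(
                accession=accession,
                sequence=_clean_sequence(accession, str(rec.seq)),
                signal_peptide=signal,
                keywords=keywords,
            )
        )
    if annotations:
        logger.warning(
            "skipped %d annotation row(s) with accessions absent from FASTA: %s",
            len(annotations),
            ", ".join(sorted(annotations)[:5]),
        )
    return proteome


def _read_annotations(
    path: str | Path,
) -> dict[str, tuple[tuple[int, int] | None, frozenset[str]]]:
    out: dict[str, tuple[tuple[int, int] | None, frozenset[str]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["accession", "signal_start", "signal_end", "keywords"]
        if header != expected:
            raise ProteomeError(
                f"annotation header {header} != expected {expected}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ProteomeError(
                    f"annotation line {lineno}: expected 4 fields, got {len(parts)}"
                )
            accession, s_start, s_end, kw = parts
            signal = None
            if s_start.strip() and s_end.strip():
                signal = (int(s_start), int(s_end))
            keywords = frozenset(k for k in kw.split(";") if k)
            out[accession] = (signal, keywords)
    return out


def read_known_sites(
    path: str | Path, proteome: ProteomeSet
) -> list[KnownSite]:
    """Read a known-site TSV and compute atypical flags against the proteome.

    Header: ``accession  position  evidence  source``.  Sites on unknown
    accessions or with positions outside the sequence are rejected with a
    logged count.
    """
    # local import: sequon predicate lives with the classifier
    from .engine import is_valid_window

    sites: list[KnownSite] = []
    n_unknown = n_out_of_range = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["accession", "position", "evidence", "source"]
        if header != expected:
            raise ProteomeError(f"known-site header {header} != {expected}")
        for line in fh:
            if not line.strip():
                continue
            accession, pos_s, evidence, source = line.rstrip("\n").split("\t")
            if accession not in proteome:
                n_unknown += 1
                continue
            position = int(pos_s)
            record = proteome[accession]
            if not 1 <= position <= record.length:
                n_out_of_range += 1
                continue
            if position + 2 <= record.length:
                window = record.sequence[position - 1 : position + 2]
                atypical = not is_valid_window(*window)
            else:
                atypical = True  # window runs off the C-terminus
            sites.append(
                KnownSite(
                    accession=accession,
                    position=position,
                    evidence=evidence,
                    source=source,
                    atypical=atypical,
                )
            )
    if n_unknown or n_out_of_range:
        logger.warning(
            "rejected known sites: %d unknown accession, %d out of range",
            n_unknown,
            n_out_of_range,
        )
    return sites


def write_proteome(
    proteome: ProteomeSet,
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    line_width: int = 60,
) -> None:
    """Write a ProteomeSet back to FASTA (+ annotation TSV); round-trips."""
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description="")
        for rec in sorted(proteome, key=lambda r: r.accession)
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            fh.write("accession\tsignal_start\tsignal_end\tkeywords\n")
            for rec in sorted(proteome, key=lambda r: r.accession):
                s_start = s_end = ""
                if rec.signal_peptide is not None:
                    s_start, s_end = map(str, rec.signal_peptide)
                fh.write(
                    f"{rec.accession}\t{s_start}\t{s_end}\t"
                    f"{';'.join(sorted(rec.keywords))}\n"
                )


def write_known_sites(sites: Iterable[KnownSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tposition\tevidence\tsource\n")
        for s in sorted(sites, key=lambda s: (s.accession, s.position)):
            fh.write(f"{s.accession}\t{s.position}\t{s.evidence}\t{s.source}\n")
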
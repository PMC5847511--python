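"""Sequon detection and loss/gain-of-glycosylation classification.

The N-linked glycosylation sequon is the tripeptide N-X-S/T where X is
any residue except proline.  A single amino-acid substitution can
abolish an existing sequon (LOG: N lost at slot 1, S/T lost at slot 3,
or P introduced at slot 2) or create a new one (GOG: N gained at slot 1,
S/T gained at slot 3, or P removed from an NPS/T context).  S<->T
exchanges at slot 3 leave the sequon intact and are never called.

Two classifiers are provided.  ``classify_impact`` is canonical: it
diffs the sequon inventory before and after the substitution, which is
unambiguous even for compound events (one substitution simultaneously
destroying one sequon and creating another, as in NSTSS + T3N).
``classify_impact_rules`` is an independent rule-table implementation of
the six named transitions, kept as a cross-checking oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ._alphabet import SLOT2_FORBIDDEN, STANDARD_AA
from .proteome import ProteinRecord

VARIANT_ORIGINS = frozenset({"somatic", "germline"})

#: overlapping-match scan for N[not P/ambiguous][S or T]
_SEQUON_RE = re.compile(r"(?=N[^PXBZJ][ST])")

RULE_LABELS = {
    ("LOG", 1): "n_lost",
    ("LOG", 2): "p_gained",
    ("LOG", 3): "st_lost",
    ("GOG", 1): "n_gained",
    ("GOG", 2): "p_lost",
    ("GOG", 3): "st_gained",
}


class RefMismatchError(ValueError):
    """Variant reference residue disagrees with the sequence."""

    def __init__(self, accession: str, position: int, expected: str, found: str):
        self.accession = accession
        self.position = position
        self.expected = expected
        self.found = found
        super().__init__(
            f"{accession} position {position}: variant reference {expected!r} "
            f"but sequence has {found!r}"
        )


@dataclass(frozen=True)
class Sequon:
    """One NXS/T site, identified by the 1-based position of its N."""

    accession: str
    start: int
    motif: str

    def __post_init__(self) -> None:
        if not is_valid_window(*self.motif):
            raise ValueError(f"{self.motif!r} is not a valid sequon window")

    @property
    def end(self) -> int:
        return self.start + 2


@dataclass(frozen=True)
class VariantRecord:
    """A single amino-acid substitution with provenance annotation."""

    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    origin: str
    sources: frozenset[str] = frozenset()
    doids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"{self.key}: ref and alt residues are equal")
        for aa, name in ((self.ref_aa, "ref"), (self.alt_aa, "alt")):
            if aa not in STANDARD_AA:
                raise ValueError(f"{name} residue {aa!r} is not a standard amino acid")
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.origin not in VARIANT_ORIGINS:
            raise ValueError(f"origin must be somatic|germline, got {self.origin!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key: the substitution itself, ignoring provenance."""
        return (self.accession, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True)
class ImpactCall:
    """One LOG or GOG event linking a variant to a sequon position."""

    variant_key: tuple[str, int, str, str]
    effect: str  # "LOG" | "GOG"
    sequon_start: int
    slot: int  # 1 = N, 2 = X, 3 = S/T
    rule: str

    def __post_init__(self) -> None:
        if self.effect not in ("LOG", "GOG"):
            raise ValueError(f"effect must be LOG|GOG, got {self.effect!r}")
        if self.slot != self.variant_key[1] - self.sequon_start + 1:
            raise ValueError("slot inconsistent with variant and sequon positions")
        if self.slot not in (1, 2, 3):
            raise ValueError(f"slot must be 1..3, got {self.slot}")

    @property
    def accession(self) -> str:
        return self.variant_key[0]

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.variant_key[0], self.sequon_start)


def is_valid_window(a: str, b: str, c: str) -> bool:
    """True iff the tripeptide a-b-c is an NXS/T (X != P) sequon.

    Windows containing any ambiguity code (X/B/Z/J) are never sequons;
    U and O behave as ordinary residues that match none of N, S, T.
    """
    return a == "N" and b not in SLOT2_FORBIDDEN and c in "ST"


def scan_sequence(sequence: str) -> list[int]:
    """All sequon start positions (1-based) in a raw sequence string."""
    return [m.start() + 1 for m in _SEQUON_RE.finditer(sequence)]


def scan_sequons(record: ProteinRecord) -> list[Sequon]:
    """All sequons of a protein, ascending by start; overlaps all reported."""
    return [
        Sequon(record.accession, start, record.sequence[start - 1 : start + 2])
        for start in scan_sequence(record.sequence)
    ]


def apply_substitution(record: ProteinRecord, variant: VariantRecord) -> str:
    """Return the sequence with the substitution applied.

    Raises :class:`RefMismatchError` when the variant's reference residue
    disagrees with the sequence (version drift between databases); the
    caller decides the skip policy.
    """
    if variant.position > record.length:
        raise IndexError(
            f"{record.accession}: variant position {variant.position} beyond "
            f"length {record.length}"
        )
    found = record.residue(variant.position)
    if found != variant.ref_aa:
        raise RefMismatchError(record.accession, variant.position, variant.ref_aa, found)
    i = variant.position - 1
    return record.sequence[:i] + variant.alt_aa + record.sequence[i + 1 :]


def slot_of(sequon_start: int, variant_position: int) -> int:
    """Slot (1=N, 2=X, 3=S/T) of a variant inside a sequon window."""
    slot = variant_position - sequon_start + 1
    if slot not in (1, 2, 3):
        raise ValueError(
            f"position {variant_position} outside sequon window starting at "
            f"{sequon_start}"
        )
    return slot


def _window_starts(position: int, length: int) -> range:
    """Starts of the (at most three) windows covering a position."""
    return range(max(1, position - 2), min(length - 2, position) + 1)


def classify_impact(record: ProteinRecord, variant: VariantRecord) -> list[ImpactCall]:
    """LOG/GOG calls for one substitution, by diffing sequon inventories.

    A start present before but not after the substitution is a LOG; a
    start present only after is a GOG.  Only windows covering the variant
    position can change, so the diff is evaluated locally.  Calls are
    ordered by sequon start.
    """
    alt_seq = apply_substitution(record, variant)  # raises on ref mismatch
    ref_seq = record.sequence
    calls: list[ImpactCall] = []
    for s in _window_starts(variant.position, record.length):
        i = s - 1
        ref_valid = is_valid_window(ref_seq[i], ref_seq[i + 1], ref_seq[i + 2])
        alt_valid = is_valid_window(alt_seq[i], alt_seq[i + 1], alt_seq[i + 2])
        if ref_valid == alt_valid:
            continue
        effect = "LOG" if ref_valid else "GOG"
        slot = slot_of(s, variant.position)
        calls.append(
            ImpactCall(
                variant_key=variant.key,
                effect=effect,
                sequon_start=s,
                slot=slot,
                rule=RULE_LABELS[(effect, slot)],
            )
        )
    return calls


def classify_impact_rules(
    record: ProteinRecord, variant: VariantRecord
) -> list[ImpactCall]:
    """Rule-table classifier implementing the six named transitions.

    Independent of :func:`classify_impact`; used as a test oracle and
    required to return an identical call set.
    """
    found = record.residue(variant.position) if variant.position <= record.length else None
    if found is None:
        raise IndexError(
            f"{record.accession}: variant position {variant.position} beyond "
            f"length {record.length}"
        )
    if found != variant.ref_aa:
        raise RefMismatchError(record.accession, variant.position, variant.ref_aa, found)

    seq = record.sequence
    ref, alt = variant.ref_aa, variant.alt_aa
    calls: list[ImpactCall] = []
    for s in _window_starts(variant.position, record.length):
        i = s - 1
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        slot = slot_of(s, variant.position)
        effect = rule = None
        if slot == 1:
            if is_valid_window(a, b, c) and alt != "N":
                effect, rule = "LOG", "n_lost"
            elif a != "N" and alt == "N" and b not in SLOT2_FORBIDDEN and c in "ST":
                effect, rule = "GOG", "n_gained"
        elif slot == 2:
            if is_valid_window(a, b, c) and alt == "P":
                effect, rule = "LOG", "p_gained"
            elif a == "N" and b == "P" and c in "ST" and alt != "P":
                effect, rule = "GOG", "p_lost"
        else:  # slot == 3
            if is_valid_window(a, b, c) and alt not in "ST":
                effect, rule = "LOG", "st_lost"
            elif (
                c not in "ST"
                and alt in "ST"
                and a == "N"
                and b not in SLOT2_FORBIDDEN
            ):
                effect, rule = "GOG", "st_gained"
        if effect is not None:
            calls.append(
                ImpactCall(
                    variant_key=variant.key,
                    effect=effect,
                    sequon_start=s,
                    slot=slot,
                    rule=rule,
                )
            )
    return calls


def classify_cohort(
    proteome, variants, classifier=classify_impact
) -> tuple[list[ImpactCall], list[VariantRecord]]:
    """Classify every variant of a cohort against a proteome.

    Returns (calls, skipped) where ``skipped`` collects variants whose
    accession is unknown, whose position is out of range, or whose
    reference residue mismatches the sequence.
    """
    calls: list[ImpactCall] = []
    skipped: list[VariantRecord] = []
    for v in variants:
        if v.accession not in proteome:
            skipped.append(v)
            continue
        record = proteome[v.accession]
        if v.position > record.length:
            skipped.append(v)
            continue
        try:
            calls.extend(classifier(record, v))
        except RefMismatchError:
            skipped.append(v)
    return calls, skipped
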
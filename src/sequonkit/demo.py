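"""Bundled demonstration cohort of recurrent cancer glycosylation variants.

A small curated set of somatic substitutions reported across three or
more cancer types that abolish (LOG) or create (GOG) N-glycosylation
sequons on secreted or membrane proteins — e.g. the KIT N486D loss and
the MUC2 T1750N gain.  The variant coordinates, residues and cancer
Disease Ontology annotations are real; the protein sequences are
SYNTHETIC stand-ins (alanine filler with the relevant sequon context
planted at the documented positions), sufficient to exercise the
classifier and ranking logic at desk scale without downloading any
proteome release.
"""

from __future__ import annotations

from .cohort import VariantCohort, merge_variants
from .engine import VariantRecord
from .proteome import KnownSite, ProteinRecord, ProteomeSet

# accession, gene, position, ref, alt, DOIDs — LOG variants hitting
# database-annotated sequons, each seen in >= 3 cancer types
LOG_VARIANTS: tuple[tuple[str, str, int, str, str, tuple[str, ...]], ...] = (
    ("O15244", "SLC22A2", 74, "T", "M", ("DOID:1793", "DOID:1319", "DOID:219")),
    ("O15438", "ABCC3", 1009, "S", "F", ("DOID:4159", "DOID:10534", "DOID:3571")),
    ("O75473", "LGR5", 77, "N", "S", ("DOID:219", "DOID:1324", "DOID:5672")),
    ("P10163", "PRB4", 110, "S", "P", ("DOID:1319", "DOID:3070", "DOID:11934")),
    ("P10721", "KIT", 486, "N", "D",
     ("DOID:184", "DOID:1993", "DOID:219", "DOID:5672")),
    ("P28472", "GABRB3", 107, "T", "M",
     ("DOID:0060119", "DOID:10534", "DOID:11934")),
    ("Q96S37", "SLC22A12", 104, "T", "M", ("DOID:1319", "DOID:10534", "DOID:219")),
    ("Q9NTG1", "PKDREJ", 297, "S", "L",
     ("DOID:4159", "DOID:0060119", "DOID:11934")),
    ("Q9NTG1", "PKDREJ", 925, "S", "L", ("DOID:10534", "DOID:219", "DOID:5672")),
    ("Q9NUN5", "LMBRD1", 349, "S", "C", ("DOID:1319", "DOID:1324", "DOID:3070")),
    ("Q9P121", "NTM", 46, "T", "M", ("DOID:0060119", "DOID:5041", "DOID:11934")),
    ("Q9UKZ4", "TENM1", 1759, "S", "L",
     ("DOID:4362", "DOID:0060119", "DOID:11934")),
    ("Q9UPZ6", "THSD7A", 236, "T", "M",
     ("DOID:0060119", "DOID:1993", "DOID:5041", "DOID:11934")),
)

# GOG variants creating sequons on viable proteins, each in >= 3 cancers
GOG_VARIANTS: tuple[tuple[str, str, int, str, str, tuple[str, ...]], ...] = (
    ("O14522", "PTPRT", 281, "A", "T", ("DOID:1319", "DOID:10534", "DOID:3070")),
    ("O43526", "KCNQ2", 785, "D", "N", ("DOID:1793", "DOID:1612", "DOID:10283")),
    ("O43699", "SIGLEC6", 251, "A", "T", ("DOID:1319", "DOID:219", "DOID:3070")),
    ("O60469", "DSCAM", 213, "A", "T",
     ("DOID:363", "DOID:1612", "DOID:1793", "DOID:5041")),
    ("O94973", "AP2A2", 115, "A", "T", ("DOID:1612", "DOID:219", "DOID:5672")),
    ("P04264", "KRT1", 248, "D", "N", ("DOID:4159", "DOID:2394", "DOID:5672")),
    ("P07357", "C8A", 169, "D", "N", ("DOID:4159", "DOID:363", "DOID:1909")),
    ("P10721", "KIT", 566, "N", "S", ("DOID:1993", "DOID:263", "DOID:5672")),
    ("P21802", "FGFR2", 659, "K", "N", ("DOID:363", "DOID:1612", "DOID:1324")),
    ("P21817", "RYR1", 2861, "D", "N",
     ("DOID:8618", "DOID:1793", "DOID:363", "DOID:11934")),
    ("P46531", "NOTCH1", 465, "A", "T",
     ("DOID:219", "DOID:3070", "DOID:5041", "DOID:11934", "DOID:0060119",
      "DOID:1319")),
    ("P54852", "EMP3", 42, "D", "N", ("DOID:8618", "DOID:0060119", "DOID:11934")),
    ("Q02817", "MUC2", 1750, "T", "N",
     ("DOID:1612", "DOID:3571", "DOID:1781", "DOID:2394", "DOID:10283",
      "DOID:1319", "DOID:1993")),
    ("Q13002", "GRIK2", 528, "D", "N", ("DOID:8618", "DOID:1612", "DOID:11054")),
    ("Q13349", "ITGAD", 1070, "D", "N",
     ("DOID:363", "DOID:1993", "DOID:219", "DOID:5672")),
    ("Q4ZHG4", "FNDC1", 253, "K", "N", ("DOID:363", "DOID:1793", "DOID:1993")),
    ("Q685J3", "MUC17", 2784, "T", "N",
     ("DOID:2394", "DOID:11934", "DOID:0060119")),
    ("Q6P1J6", "PLB1", 645, "D", "N", ("DOID:363", "DOID:0060119", "DOID:11934")),
    ("Q6UWW8", "CES3", 161, "D", "N", ("DOID:4159", "DOID:219", "DOID:5672")),
    ("Q6UX06", "OLFM4", 372, "R", "S", ("DOID:1793", "DOID:1612", "DOID:5041")),
    ("Q7Z304", "MAMDC2", 319, "D", "N", ("DOID:4159", "DOID:1612", "DOID:11054")),
    ("Q7Z5H5", "VN1R4", 265, "L", "S", ("DOID:4362", "DOID:1793", "DOID:11934")),
    ("Q86TH1", "ADAMTSL2", 44, "D", "N", ("DOID:10534", "DOID:219", "DOID:5672")),
    ("Q8IZD2", "KMT2E", 902, "D", "N", ("DOID:363", "DOID:219", "DOID:5672")),
    ("Q8N158", "GPC2", 200, "D", "N", ("DOID:1612", "DOID:5041", "DOID:5672")),
    ("Q8N8F6", "YIPF7", 141, "D", "N",
     ("DOID:4362", "DOID:0060119", "DOID:11934")),
    ("Q8NFZ4", "NLGN2", 542, "A", "T", ("DOID:8618", "DOID:0060119", "DOID:11934")),
    ("Q8NGZ4", "OR2G3", 159, "H", "N", ("DOID:363", "DOID:219", "DOID:1324")),
    ("Q8TC71", "SPATA18", 404, "K", "N",
     ("DOID:363", "DOID:1319", "DOID:1793", "DOID:1324")),
    ("Q8TDM6", "DLG5", 1799, "D", "N", ("DOID:363", "DOID:0060119", "DOID:11934")),
    ("Q92556", "ELMO1", 55, "D", "N", ("DOID:4159", "DOID:1319", "DOID:3070")),
    ("Q92736", "RYR2", 898, "I", "T", ("DOID:0060119", "DOID:1324", "DOID:11934")),
    ("Q96PZ7", "CSMD1", 3053, "D", "N", ("DOID:4159", "DOID:10534", "DOID:219")),
    ("Q9BXX0", "EMILIN2", 759, "K", "N", ("DOID:363", "DOID:1324", "DOID:11054")),
    ("Q9H2B2", "SYT4", 89, "K", "N", ("DOID:363", "DOID:1612", "DOID:219")),
    ("Q9H9P2", "CHODL", 186, "P", "S", ("DOID:4159", "DOID:1612", "DOID:1324")),
    ("Q9UKJ8", "ADAM21", 278, "D", "N", ("DOID:4159", "DOID:219", "DOID:5672")),
    ("Q9UQP3", "TNN", 1091, "D", "N", ("DOID:0060119", "DOID:1324", "DOID:11934")),
    ("Q9Y5F1", "PCDHB12", 556, "D", "N", ("DOID:363", "DOID:4159", "DOID:10534")),
)

_FILLER = "A"


def _context_edits(position: int, ref: str, alt: str, effect: str):
    """Residue edits planting the minimal sequon context for one variant.

    LOG variants sit inside an existing sequon (slot 1 when ref is N,
    slot 3 when ref is S/T); GOG variants sit where the substitution
    will complete a sequon (slot 1 for gained N, slot 2 for a removed P
    in an NPS/T context, slot 3 for gained S/T).
    """
    if effect == "LOG":
        if ref == "N":
            return {position: "N", position + 1: _FILLER, position + 2: "T"}
        if ref in "ST":
            return {position - 2: "N", position - 1: _FILLER, position: ref}
        raise ValueError(f"no LOG context rule for reference residue {ref!r}")
    # GOG
    if alt == "N":
        return {position: ref, position + 1: _FILLER, position + 2: "T"}
    if alt in "ST":
        if ref == "P":
            return {position - 1: "N", position: "P", position + 1: "T"}
        return {position - 2: "N", position - 1: _FILLER, position: ref}
    raise ValueError(f"no GOG context rule for alternate residue {alt!r}")


def demo_proteome() -> ProteomeSet:
    """Synthetic-context proteome for the bundled variant set.

    Every protein is alanine filler with the documented sequon contexts
    planted; all are annotated with the Membrane keyword (and a signal
    peptide for the first half of accessions) so the viability filter
    keeps them.  Known-site entries are attached for each LOG sequon.
    """
    edits: dict[str, dict[int, str]] = {}
    for table, effect in ((LOG_VARIANTS, "LOG"), (GOG_VARIANTS, "GOG")):
        for accession, _gene, position, ref, alt, _doids in table:
            edits.setdefault(accession, {}).update(
                _context_edits(position, ref, alt, effect)
            )
    proteome = ProteomeSet()
    for i, accession in enumerate(sorted(edits)):
        protein_edits = edits[accession]
        length = max(protein_edits) + 5
        residues = [_FILLER] * length
        for pos, aa in protein_edits.items():
            residues[pos - 1] = aa
        proteome.add(
            ProteinRecord(
                accession=accession,
                sequence="".join(residues),
                signal_peptide=(1, 22) if i % 2 == 0 else None,
                keywords=frozenset({"Membrane"}),
            )
        )
    proteome.known_sites = demo_known_sites()
    return proteome


def demo_known_sites() -> list[KnownSite]:
    """Database-annotated sites backing the LOG variants (high confidence)."""
    sites = []
    for accession, _gene, position, ref, _alt, _doids in LOG_VARIANTS:
        start = position if ref == "N" else position - 2
        sites.append(
            KnownSite(
                accession=accession,
                position=start,
                evidence="experimental",
                source="uniprot_ft",
                atypical=False,
            )
        )
    return sites


def _records(table, origin: str) -> list[VariantRecord]:
    return [
        VariantRecord(
            accession=accession,
            position=position,
            ref_aa=ref,
            alt_aa=alt,
            origin=origin,
            sources=frozenset({"cosmic", "tcga", "icgc", "intogen"}),
            doids=frozenset(doids),
        )
        for accession, _gene, position, ref, alt, doids in table
    ]


def demo_somatic_cohort() -> VariantCohort:
    """The bundled LOG + GOG variants as one somatic cohort."""
    return merge_variants(
        [_records(LOG_VARIANTS, "somatic"), _records(GOG_VARIANTS, "somatic")],
        origin_label="somatic",
    )


def demo_log_cohort() -> VariantCohort:
    return merge_variants([_records(LOG_VARIANTS, "somatic")], origin_label="somatic")


def demo_gog_cohort() -> VariantCohort:
    return merge_variants([_records(GOG_VARIANTS, "somatic")], origin_label="somatic")
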
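# sequonkit

Analysis of N-linked glycosylation sequons in proteomes and of the single
amino-acid substitutions that destroy or create them.

N-glycans attach to the asparagine of the consensus tripeptide
**N-X-S/T (X ≠ P)** — the *sequon*. A nonsynonymous variant can abolish an
existing sequon (**LOG**, loss of glycosylation: N lost at slot 1, S/T lost
at slot 3, or P introduced at slot 2) or create a new one (**GOG**, gain:
N gained at slot 1, S/T gained at slot 3, or P removed from an NPS/T
context). S↔T exchanges at slot 3 keep the sequon intact and are never
called. Because altered glycosylation is a recurring theme in cancer
biology, the package also aggregates somatic-only impact calls across
cancer types (Disease Ontology terms) and ranks candidate biomarker
variants by how many cancers they recur in.

`sequonkit` is aimed at computational glycobiologists and cancer-genomics
analysts who have protein-level variant tables (accession, position, ref,
alt) and want reproducible sequon inventories, LOG/GOG calls, and
pan-cancer summary tables.

## What it does

- **Scan** proteomes (FASTA) for all overlapping NXS/T (X ≠ P) sequons;
  windows containing ambiguity codes (X/B/Z/J) are never called.
- **Classify** substitutions as LOG/GOG by diffing the sequon inventory
  before and after the edit; an independent rule-table classifier serves as
  a built-in cross-check.
- **Partition** variant cohorts: merge multi-database tables on the
  substitution key and compute the somatic-only subset (somatic keys absent
  from the germline set).
- **Aggregate**: biological-viability filter (signal peptide or
  Secreted/Membrane keyword), high-confidence restriction to
  database-annotated sites, multi-cancer ranking, sequon spacing and
  density summaries, slot distributions, occupancy rates, and an exact
  two-sided binomial enrichment test.
- **Simulate** proteomes and cohorts with planted, labeled LOG/GOG/neutral
  variants so the whole pipeline is testable offline.

## Worked example

```python
from sequonkit import (ProteinRecord, VariantRecord, classify_impact,
                       scan_sequence)

# prion-protein-like context: N-I-T sequon at 181..183
record = ProteinRecord("PRNP", "A" * 180 + "NIT" + "A" * 4)
variant = VariantRecord(accession="PRNP", position=183, ref_aa="T",
                        alt_aa="A", origin="germline")
print(scan_sequence(record.sequence))
print(classify_impact(record, variant))
```

prints

```
[181]
[ImpactCall(variant_key=('PRNP', 183, 'T', 'A'), effect='LOG', sequon_start=181, slot=3, rule='st_lost')]
```

i.e. the T183A substitution removes the S/T at slot 3 of the sequon
starting at 181, so the site is reported as a loss of glycosylation — the
classic encephalopathy-associated loss in the prion protein.

The same workflow runs from the shell:

```bash
sequonkit simulate --out-dir sim --n-proteins 100 --seed 1
sequonkit run --fasta sim/proteome.fasta --annotations sim/annotations.tsv \
    --known-sites sim/known_sites.tsv --somatic sim/somatic.tsv \
    --germline sim/germline.tsv --out results/
```

which writes the sequon inventory, per-cohort impact calls, count
summaries, multi-cancer ranking tables, density/spacing/slot summaries,
and a rejection report as deterministic TSVs.

## Layout

- `src/sequonkit/proteome.py` — FASTA/annotation/known-site containers and readers
- `src/sequonkit/engine.py` — sequon predicate, scanner, LOG/GOG classifiers
- `src/sequonkit/cohort.py` — variant tables, merging, somatic-only subtraction
- `src/sequonkit/stats.py` — filters, rankings, spacing/density/occupancy, binomial test
- `src/sequonkit/simulate.py` — synthetic proteomes and cohorts with planted truth
- `src/sequonkit/demo.py` — bundled multi-cancer demonstration variant set
- `src/sequonkit/pipeline.py`, `src/sequonkit/cli.py` — orchestration and CLI

See `docs/methods.md` for the underlying model, parameter choices, and
limitations.
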
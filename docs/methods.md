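# Methods

## The sequon model

N-linked glycosylation initiates at the asparagine of the consensus
tripeptide N-X-S/T, where X is any residue except proline. The package
treats this string predicate as the complete site model: a *sequon* is
any 3-residue window `seq[i..i+2]` with `seq[i] == 'N'`,
`seq[i+1] != 'P'` and `seq[i+2] in {'S','T'}`, identified by the 1-based
position of its N. Overlapping sequons (e.g. `NNSS` at 1 and 2) are all
reported. Atypical sites such as NXC are real but rare glycobiology;
annotated positions whose window fails the predicate are flagged
`atypical` and excluded from all classification and occupancy counts —
they are never silently treated as sequons.

Ambiguity policy: a window containing any of the alphabet ambiguity codes
X/B/Z/J is never asserted to be a sequon (we refuse to call a motif on
uncertain sequence), while the rare translated residues U and O are
ordinary residues that simply never match N, S or T. All coordinates are
1-based with closed intervals, the convention of protein variant notation
(T183A = position 183) and of UniProt feature lines.

## LOG/GOG classification

A substitution at position *p* can only change the validity of the (at
most three) windows starting at *p−2 … p*. The canonical classifier
diffs window validity before and after the substitution: a window valid
only before is a **LOG**, valid only after a **GOG**. This is exactly
the set difference of full before/after sequon scans, and it handles
compound events correctly — in `NSTSS`, T3N simultaneously destroys the
sequon at 1 (slot 3) and creates one at 3 (slot 1). The *slot* of a call
is the position of the variant inside the window (1 = N, 2 = X,
3 = S/T), and the rule label is determined by effect and slot
(`n_lost`, `p_gained`, `st_lost`; `n_gained`, `p_lost`, `st_gained`).
S↔T exchanges at slot 3 leave validity unchanged on both sides of the
diff, so they generate no call by construction.

A second, structurally independent classifier implements the six rules
directly as per-window condition tables. The two must agree exactly;
this dual implementation is enforced by a randomized equivalence test
over 10⁵ (sequence, variant) pairs and guards both against rule
omissions and against diff bookkeeping errors. Classification also
satisfies a conservation law used as a property test:
`|scan(alt)| = |scan(ref)| − #LOG + #GOG`.

Variants whose stated reference residue disagrees with the sequence
(database/proteome version drift) raise a typed `RefMismatchError` and
are excluded and counted in a rejection report rather than guessed at.

## Cohorts and the somatic-only subset

Variant identity is the substitution key (accession, position, ref,
alt); provenance (origin, source databases, disease terms) is annotation
and is unioned when records with equal keys are merged. The
*somatic-only* cohort is the set difference of somatic and germline keys
— a somatic call that also occurs as a germline polymorphism is removed
before pan-cancer analysis, since it cannot be treated as
tumor-specific. Disease Ontology identifiers are opaque strings; a
variant's cancer count is the number of distinct DOIDs annotated on it,
and no ontology traversal is attempted (tissue- and cell-level terms may
legitimately co-occur on one variant).

## Filters, rankings and summary statistics

- **Viability filter**: a protein is a plausible glycosylation substrate
  if it has a signal peptide or carries the keyword Secreted or
  Membrane. Cytoplasmic/nuclear proteins without a signal peptide are
  excluded from ranking tables (a created sequon on such a protein is
  unlikely to ever see the oligosaccharyltransferase machinery).
- **High confidence**: a LOG call is high-confidence when its sequon is
  a database-annotated, non-atypical site. GOG calls are never
  high-confidence — a newly created sequon cannot pre-exist in site
  databases.
- **Multi-cancer table**: calls on viable proteins with at least
  `min_cancers` (default 3) distinct DOIDs, sorted by cancer count
  descending with deterministic tie-breaks (accession, then position
  ascending) so outputs are byte-reproducible.
- **Spacing**: gaps between consecutive sequon starts within a protein,
  pooled across proteins; overlapping sequons give the minimum possible
  gap of 1. The standard deviation is the sample (n−1) estimate. The
  alternative per-protein statistic length/sequon-count is available
  separately as `residues_per_event` in the density ranking.
- **Density**: events per residue per protein, ranked densest first;
  zero-event proteins are omitted (their reciprocal is undefined).
- **Occupancy**: unique non-atypical known sites divided by total
  sequons; the glycoprotein-restricted variant divides sites by sequons
  on proteins that carry at least one known site ("glycoprotein" =
  at least one occupied, non-atypical sequon).
- **Binomial enrichment**: exact two-sided test, minimum-likelihood
  method (the p-value sums all outcome probabilities not exceeding the
  point probability of the observed count). Two-sidedness is a package
  choice; the implementation delegates to `scipy.stats.binomtest` and is
  verified against full enumeration for all n ≤ 20.

## Synthetic data

The generator emulates the statistical regime of the reviewed human
proteome so that all pipeline stages can be exercised offline:

- **Composition**: residues drawn i.i.d. from human background amino-acid
  frequencies (bundled constant table); a chi-square goodness-of-fit test
  at α = 0.01 on ≥10⁵ pooled residues is part of the test suite.
- **Lengths**: log-normal with mean 560 and sd 520 residues (clamped to
  [30, 8000]), approximating the right-skewed human length distribution.
- **Sequon density**: target one sequon per 118 residues by default, the
  average density of the human proteome; i.i.d. composition alone yields
  roughly one per 215, so sequons are planted (or ablated for low
  targets) by local 3-residue edits, re-scanning after every edit, until
  the pooled density matches the target within 10%. Truth records the
  final scan, not the planting intent, so it is always consistent with
  the engine's semantics.
- **Variants**: LOG variants are drawn from the three loss rules over a
  configurable slot mixture (default 0.40/0.15/0.45 — slot 2 is rarest
  because only P-introduction can hit it), GOG variants from the three
  gain rules (default 45%/45%/10%, P-removal being limited by how rare
  NPS/T contexts are), and neutral variants are verified to produce no
  calls. Every candidate is validated with the *rule-table* classifier
  (not the canonical diff classifier, to keep the check independent) and
  must yield exactly its single expected call; compound or colliding
  candidates are redrawn. A configurable fraction of somatic keys
  (default 0.1) is duplicated into the germline cohort and must vanish
  from the somatic-only subset.
- **Cancer annotation**: each variant receives 1–8 distinct DOIDs
  (default law skewed toward 1–2) sampled from a bundled 38-term cancer
  slim palette of opaque identifiers.
- All generators are pure functions of seed and parameters; fixed seeds
  reproduce byte-identical FASTA/TSV bundles.

What the simulator does **not** emulate: nucleotide-level mutation
processes and trinucleotide signatures, per-gene mutation-rate
heterogeneity, homopolymer/low-complexity sequence structure, isoforms,
and correlated placement of sequons in domains. Passing the
recovery tests therefore demonstrates correctness of the string-level
pipeline (scanning, subtraction, classification, aggregation), not
biological realism of any particular variant call.

## Demonstration set

`sequonkit.demo` bundles a small curated set of recurrent somatic
LOG/GOG variants on secreted/membrane proteins (13 high-confidence
losses and 39 gains, each observed in three or more cancer types, e.g.
KIT N486D and MUC2 T1750N). Variant coordinates, residues and DOID
annotations are real; the protein sequences are synthetic stand-ins —
alanine filler with the documented sequon context planted at the right
positions — sufficient for the classifier and ranking logic and small
enough to ship as source.

## Numerical and design choices

- Deterministic ordering everywhere (sorted accessions, fixed column
  orders); identical inputs produce byte-identical outputs.
- Problem sizes in the test suite and acceptance script (proteomes of
  60–400 proteins, 10⁴–10⁵ randomized property cases) were chosen so the
  whole suite completes in well under a minute while still covering every
  rule channel; all statistics concentrate well at these sizes.
- FASTA letters are upper-cased on read; a terminal `*` stop codon is
  stripped with a warning; any other character outside the 26-letter
  alphabet is a hard error (fail fast on malformed input).
- Duplicate FASTA accessions are an error naming the accession;
  annotation/known-site/variant rows that cannot be joined are skipped
  with logged counts, never silently dropped.
- Isoforms are not modeled: each FASTA entry is treated as an independent
  protein.
- A generic published-variant lookup (`stats.published_variant_overlap`)
  joins calls to any user-supplied table of disease-associated
  substitutions by variant key; no licensed database content is shipped.
- Hooks, not reimplementations, are provided for external per-site
  predictors: the pipeline consumes only string-rule calls, and a
  predicted-site table can be supplied as ordinary known sites with
  `evidence=predicted`.

## Known limitations

- Only single amino-acid substitutions are modeled — no indels,
  frameshifts, multi-residue variants, or nucleotide-to-protein
  consequence calling.
- Atypical motifs (NXC and rarer) are flagged but never classified.
- The binomial test's null rate must be supplied by the caller; the
  package does not derive expected rates from ontology structure.
- Sequon presence is a necessary, not sufficient, condition for
  glycosylation; occupancy statistics quantify exactly this gap.
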
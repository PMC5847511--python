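"""Pan-cancer aggregation, filtering, ranking, and summary statistics.

Covers the downstream analysis of impact calls: biological-viability
filtering (signal peptide or Secreted/Membrane localisation), the
high-confidence restriction to database-annotated sites, the
multi-cancer ranking table, sequon spacing and density summaries, the
slot distribution of affected residues, occupancy rates, and an exact
binomial enrichment test.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats as sp_stats

from .engine import ImpactCall, VariantRecord
from .proteome import KnownSite, ProteomeSet

VIABILITY_KEYWORDS = frozenset({"Secreted", "Membrane"})


@dataclass(frozen=True)
class SpacingStats:
    """Summary of gaps (in residues) between consecutive sequon starts."""

    minimum: int
    maximum: int
    mean: float
    median: float
    sd: float
    n_gaps: int


@dataclass(frozen=True)
class DensityRecord:
    """Events per residue for one protein (sequons, or affected sequons)."""

    accession: str
    n_events: int
    length: int

    @property
    def density(self) -> float:
        return self.n_events / self.length

    @property
    def residues_per_event(self) -> float | None:
        return self.length / self.n_events if self.n_events else None


@dataclass(frozen=True)
class EnrichmentResult:
    k: int
    n: int
    p0: float
    p_value: float


@dataclass(frozen=True)
class MultiCancerRow:
    variant_key: tuple[str, int, str, str]
    effect: str
    sequon_start: int
    n_cancers: int
    doids: frozenset[str]
    high_confidence: bool
    viable: bool

    @property
    def accession(self) -> str:
        return self.variant_key[0]

    @property
    def position(self) -> int:
        return self.variant_key[1]


@dataclass(frozen=True)
class OccupancySummary:
    """Sequon prevalence and how often sequons are occupied by real sites."""

    fraction_proteins_with_sequon: float
    mean_sequons_per_sequon_protein: float
    occupancy: float
    glycoprotein_occupancy: float
    n_sequons: int
    n_known_sites: int


def cancer_count(variant: VariantRecord) -> int:
    """Number of distinct cancer types (DOIDs) annotated on a variant."""
    return len(variant.doids)


def viability_filter(proteome: ProteomeSet) -> set[str]:
    """Accessions where glycosylation is biologically plausible.

    A protein passes if it has a signal peptide or carries the keyword
    Secreted or Membrane.
    """
    return {
        rec.accession
        for rec in proteome
        if rec.signal_peptide is not None or (rec.keywords & VIABILITY_KEYWORDS)
    }


def known_site_index(known_sites: Iterable[KnownSite]) -> set[tuple[str, int]]:
    """Unique (accession, position) pairs of non-atypical known sites."""
    return {(s.accession, s.position) for s in known_sites if not s.atypical}


def high_confidence_filter(
    calls: Iterable[ImpactCall], known_sites: Iterable[KnownSite]
) -> list[ImpactCall]:
    """LOG calls whose sequon is a database-annotated (non-atypical) site.

    GOG calls are never high-confidence: a newly created sequon cannot
    pre-exist in site databases.
    """
    annotated = known_site_index(known_sites)
    return [
        c for c in calls if c.effect == "LOG" and c.site_key in annotated
    ]


def multicancer_table(
    calls: Iterable[ImpactCall],
    variants: Mapping[tuple[str, int, str, str], VariantRecord] | Iterable[VariantRecord],
    known_sites: Iterable[KnownSite],
    proteome: ProteomeSet,
    min_cancers: int = 3,
    viable_only: bool = True,
    high_confidence_only: bool = False,
) -> list[MultiCancerRow]:
    """Rank impact calls by the number of cancer types they appear in.

    Rows are restricted to biologically viable proteins (unless
    ``viable_only`` is disabled) with at least ``min_cancers`` distinct
    DOIDs, sorted by cancer count descending, then accession and
    position ascending.
    """
    if not isinstance(variants, Mapping):
        variants = {v.key: v for v in variants}
    viable = viability_filter(proteome)
    annotated = known_site_index(known_sites)
    rows: list[MultiCancerRow] = []
    for call in calls:
        variant = variants[call.variant_key]
        n = cancer_count(variant)
        if n < min_cancers:
            continue
        is_viable = call.accession in viable
        if viable_only and not is_viable:
            continue
        high_conf = call.effect == "LOG" and call.site_key in annotated
        if high_confidence_only and not high_conf:
            continue
        rows.append(
            MultiCancerRow(
                variant_key=call.variant_key,
                effect=call.effect,
                sequon_start=call.sequon_start,
                n_cancers=n,
                doids=variant.doids,
                high_confidence=high_conf,
                viable=is_viable,
            )
        )
    rows.sort(key=lambda r: (-r.n_cancers, r.accession, r.position))
    return rows


def spacing_stats(
    sequon_lists: Mapping[str, Sequence[int]]
) -> SpacingStats | None:
    """Pooled gaps between consecutive sequon starts within each protein.

    Proteins with fewer than two sequons contribute no gaps.  Overlapping
    sequons (e.g. NNSS) yield the minimum possible gap of 1.  Returns
    ``None`` when no protein has two or more sequons.  The standard
    deviation is the sample (n-1) estimate.
    """
    gaps: list[int] = []
    for starts in sequon_lists.values():
        ordered = sorted(starts)
        gaps.extend(b - a for a, b in zip(ordered, ordered[1:]))
    if not gaps:
        return None
    return SpacingStats(
        minimum=min(gaps),
        maximum=max(gaps),
        mean=statistics.fmean(gaps),
        median=float(statistics.median(gaps)),
        sd=statistics.stdev(gaps) if len(gaps) > 1 else 0.0,
        n_gaps=len(gaps),
    )


def density_per_protein(
    sequon_lists: Mapping[str, Sequence[int]], proteome: ProteomeSet
) -> list[DensityRecord]:
    """Events per protein length, ranked densest first.

    Proteins with zero events are omitted from the ranking (their
    residues-per-event is undefined).  Ties are broken by accession.
    """
    records = [
        DensityRecord(acc, len(starts), proteome[acc].length)
        for acc, starts in sequon_lists.items()
        if len(starts) > 0
    ]
    records.sort(key=lambda r: (-r.density, r.accession))
    return records


def slot_distribution(calls: Iterable[ImpactCall]) -> dict[str, dict[int, int]]:
    """Counts of calls per (effect, slot); always exhaustive over 1..3."""
    table = {"LOG": {1: 0, 2: 0, 3: 0}, "GOG": {1: 0, 2: 0, 3: 0}}
    for c in calls:
        table[c.effect][c.slot] += 1
    return table


def binomial_enrichment(k: int, n: int, p0: float) -> EnrichmentResult:
    """Two-sided exact binomial test (minimum-likelihood method).

    The p-value sums the probabilities of all outcomes whose point
    probability does not exceed that of the observed count ``k`` under
    Binomial(n, p0).
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    p_value = sp_stats.binomtest(k, n, p0, alternative="two-sided").pvalue
    return EnrichmentResult(k=k, n=n, p0=p0, p_value=float(min(1.0, p_value)))


def occupancy_stats(
    sequon_lists: Mapping[str, Sequence[int]],
    known_sites: Iterable[KnownSite],
    proteome: ProteomeSet,
) -> OccupancySummary:
    """Sequon prevalence and occupancy rates.

    Occupancy is the number of unique non-atypical known sites divided
    by the number of sequons; the glycoprotein occupancy restricts both
    counts to proteins carrying at least one known (non-atypical) site.
    """
    n_proteins = len(proteome)
    with_sequon = [acc for acc, starts in sequon_lists.items() if starts]
    n_sequons = sum(len(starts) for starts in sequon_lists.values())
    sites = known_site_index(known_sites)
    glyco_accessions = {acc for acc, _ in sites}
    n_glyco_sequons = sum(
        len(starts)
        for acc, starts in sequon_lists.items()
        if acc in glyco_accessions
    )
    n_glyco_sites = len(sites)
    return OccupancySummary(
        fraction_proteins_with_sequon=(
            len(with_sequon) / n_proteins if n_proteins else math.nan
        ),
        mean_sequons_per_sequon_protein=(
            n_sequons / len(with_sequon) if with_sequon else math.nan
        ),
        occupancy=len(sites) / n_sequons if n_sequons else math.nan,
        glycoprotein_occupancy=(
            n_glyco_sites / n_glyco_sequons if n_glyco_sequons else math.nan
        ),
        n_sequons=n_sequons,
        n_known_sites=len(sites),
    )


def published_variant_overlap(
    calls: Iterable[ImpactCall],
    published_keys: Iterable[tuple[str, int, str, str]],
) -> dict[str, int]:
    """Join calls to a user-supplied published-variant table by key.

    Generic lookup for comparing against any externally curated list of
    disease-associated substitutions; reports overlap counts per effect.
    """
    published = set(published_keys)
    out = {"LOG": 0, "GOG": 0}
    seen: set[tuple] = set()
    for c in calls:
        if c.variant_key in published and (c.variant_key, c.effect) not in seen:
            seen.add((c.variant_key, c.effect))
            out[c.effect] += 1
    return out
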
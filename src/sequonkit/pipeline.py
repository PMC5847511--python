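"""End-to-end orchestration: scan, classify, aggregate, write tables.

Given a proteome (FASTA + annotation TSV), known-site table, and
somatic/germline variant tables, the pipeline writes a fixed set of
deterministic TSV outputs: the sequon inventory, per-cohort impact-call
tables (somatic, germline, somatic-only), a count summary (variants /
affected sequons / affected proteins per cohort x effect), multi-cancer
ranking tables for LOG and GOG, a sequon density ranking, the spacing
summary, the slot distribution, and a rejection report.  Reruns on
identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import stats as pcstats
from .cohort import (
    RejectionReport,
    VariantCohort,
    merge_variants,
    read_variants,
    somatic_only,
    validate_against_proteome,
)
from .engine import ImpactCall, VariantRecord, classify_cohort, scan_sequons
from .proteome import read_known_sites, read_proteome

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage name when an input cannot be used."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    fasta: Path
    outdir: Path
    annotations: Path | None = None
    known_sites: Path | None = None
    somatic: Path | None = None
    germline: Path | None = None
    min_cancers: int = 3
    viable_only: bool = True
    high_confidence_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cancers < 1:
            raise ValueError("min_cancers must be >= 1")
        for name in ("fasta", "outdir", "annotations", "known_sites",
                     "somatic", "germline"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))


@dataclass
class PipelineResult:
    outputs: dict[str, Path] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def _calls_frame(
    calls: Iterable[ImpactCall],
    variants: Mapping[tuple, VariantRecord],
) -> pd.DataFrame:
    rows = []
    for c in sorted(
        calls, key=lambda c: (c.variant_key, c.effect, c.sequon_start)
    ):
        v = variants[c.variant_key]
        rows.append(
            {
                "accession": c.accession,
                "position": c.variant_key[1],
                "ref": c.variant_key[2],
                "alt": c.variant_key[3],
                "effect": c.effect,
                "sequon_start": c.sequon_start,
                "slot": c.slot,
                "rule": c.rule,
                "origin": v.origin,
                "sources": ";".join(sorted(v.sources)),
                "doids": ";".join(sorted(v.doids)),
            }
        )
    columns = [
        "accession", "position", "ref", "alt", "effect", "sequon_start",
        "slot", "rule", "origin", "sources", "doids",
    ]
    return pd.DataFrame(rows, columns=columns)


def _multicancer_frame(rows: list[pcstats.MultiCancerRow]) -> pd.DataFrame:
    columns = [
        "accession", "position", "ref", "alt", "effect", "sequon_start",
        "n_cancers", "doids", "high_confidence", "viable",
    ]
    return pd.DataFrame(
        [
            {
                "accession": r.accession,
                "position": r.position,
                "ref": r.variant_key[2],
                "alt": r.variant_key[3],
                "effect": r.effect,
                "sequon_start": r.sequon_start,
                "n_cancers": r.n_cancers,
                "doids": ";".join(sorted(r.doids)),
                "high_confidence": r.high_confidence,
                "viable": r.viable,
            }
            for r in rows
        ],
        columns=columns,
    )


def summarize_counts(
    calls_by_cohort: Mapping[str, Iterable[ImpactCall]]
) -> pd.DataFrame:
    """Distinct variants / affected sequons / affected proteins per cell.

    For every cohort x effect cell the counts obey
    variants >= sequons >= proteins: several substitutions can hit one
    sequon, and a protein can carry several affected sequons.
    """
    rows = []
    for cohort in sorted(calls_by_cohort):
        calls = list(calls_by_cohort[cohort])
        for effect in ("LOG", "GOG"):
            subset = [c for c in calls if c.effect == effect]
            rows.append(
                {
                    "cohort": cohort,
                    "effect": effect,
                    "n_variants": len({c.variant_key for c in subset}),
                    "n_sequons": len({c.site_key for c in subset}),
                    "n_proteins": len({c.accession for c in subset}),
                }
            )
    return pd.DataFrame(
        rows, columns=["cohort", "effect", "n_variants", "n_sequons", "n_proteins"]
    )


def _load_cohort(path: Path | None, label: str, stage: str) -> VariantCohort:
    if path is None:
        return VariantCohort(variants=[], origin_label=label)
    try:
        records = read_variants(path)
    except OSError as exc:
        raise PipelineError(stage, str(exc)) from exc
    return merge_variants([records], origin_label=label)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write all output tables."""
    t0 = time.perf_counter()
    result = PipelineResult()
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    # --- inputs ----------------------------------------------------------
    try:
        proteome = read_proteome(config.fasta, config.annotations)
    except OSError as exc:
        raise PipelineError("read_proteome", str(exc)) from exc
    logger.info("read %d protein records", len(proteome))
    known_sites = []
    if config.known_sites is not None:
        try:
            known_sites = read_known_sites(config.known_sites, proteome)
        except OSError as exc:
            raise PipelineError("read_known_sites", str(exc)) from exc
        proteome.known_sites = known_sites
    logger.info("read %d known sites", len(known_sites))

    somatic = _load_cohort(config.somatic, "somatic", "read_somatic")
    germline = _load_cohort(config.germline, "germline", "read_germline")
    somonly = somatic_only(somatic, germline)
    logger.info(
        "cohorts: %d somatic, %d germline, %d somatic-only",
        len(somatic), len(germline), len(somonly),
    )

    # --- sequon inventory ------------------------------------------------
    sequon_lists: dict[str, list[int]] = {}
    inventory_rows = []
    for record in sorted(proteome, key=lambda r: r.accession):
        sequons = scan_sequons(record)
        sequon_lists[record.accession] = [s.start for s in sequons]
        for s in sequons:
            inventory_rows.append(
                {"accession": s.accession, "start": s.start, "motif": s.motif}
            )
    inventory = pd.DataFrame(
        inventory_rows, columns=["accession", "start", "motif"]
    )
    _write(result, outdir, "sequons", inventory)
    result.counts["sequons"] = len(inventory)
    logger.info("scanned %d sequons", len(inventory))

    # --- classification --------------------------------------------------
    calls_by_cohort: dict[str, list[ImpactCall]] = {}
    rejections: dict[str, RejectionReport] = {}
    variant_index: dict[tuple, VariantRecord] = {}
    for cohort in (somatic, germline, somonly):
        valid, report = validate_against_proteome(cohort, proteome)
        rejections[cohort.origin_label] = report
        calls, _ = classify_cohort(proteome, valid)
        calls_by_cohort[cohort.origin_label] = calls
        variant_index.update({v.key: v for v in cohort})
        _write(
            result, outdir, f"impact_{cohort.origin_label}",
            _calls_frame(calls, variant_index),
        )
        result.counts[f"calls_{cohort.origin_label}"] = len(calls)
        logger.info(
            "%s: %d valid variants, %d impact calls",
            cohort.origin_label, len(valid), len(calls),
        )

    # --- summaries -------------------------------------------------------
    _write(result, outdir, "counts_summary", summarize_counts(calls_by_cohort))

    so_calls = calls_by_cohort["somatic_only"]
    for effect in ("LOG", "GOG"):
        rows = pcstats.multicancer_table(
            [c for c in so_calls if c.effect == effect],
            variant_index,
            known_sites,
            proteome,
            min_cancers=config.min_cancers,
            viable_only=config.viable_only,
            high_confidence_only=config.high_confidence_only,
        )
        _write(
            result, outdir, f"multicancer_{effect.lower()}",
            _multicancer_frame(rows),
        )
        result.counts[f"multicancer_{effect.lower()}"] = len(rows)

    density = pcstats.density_per_protein(sequon_lists, proteome)
    _write(
        result, outdir, "density_ranking",
        pd.DataFrame(
            [
                {
                    "accession": d.accession,
                    "n_sequons": d.n_events,
                    "length": d.length,
                    "density": round(d.density, 6),
                    "residues_per_sequon": round(d.residues_per_event, 2),
                }
                for d in density
            ],
            columns=[
                "accession", "n_sequons", "length", "density",
                "residues_per_sequon",
            ],
        ),
    )

    spacing = pcstats.spacing_stats(sequon_lists)
    spacing_frame = pd.DataFrame(
        [
            {
                "minimum": spacing.minimum,
                "maximum": spacing.maximum,
                "mean": round(spacing.mean, 2),
                "median": spacing.median,
                "sd": round(spacing.sd, 2),
                "n_gaps": spacing.n_gaps,
            }
        ]
        if spacing is not None
        else [],
        columns=["minimum", "maximum", "mean", "median", "sd", "n_gaps"],
    )
    _write(result, outdir, "spacing_summary", spacing_frame)

    slots = pcstats.slot_distribution(so_calls)
    _write(
        result, outdir, "slot_distribution",
        pd.DataFrame(
            [
                {"effect": effect, "slot": slot, "n_calls": slots[effect][slot]}
                for effect in ("LOG", "GOG")
                for slot in (1, 2, 3)
            ]
        ),
    )

    _write(
        result, outdir, "rejections",
        pd.DataFrame(
            [
                {"cohort": label, **report.as_dict()}
                for label, report in sorted(rejections.items())
            ]
        ),
    )

    logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    return result


def _write(result: PipelineResult, outdir: Path, name: str, frame: pd.DataFrame) -> None:
    path = outdir / f"{name}.tsv"
    frame.to_csv(path, sep="\t", index=False)
    result.outputs[name] = path
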
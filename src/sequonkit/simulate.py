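"""Synthetic proteomes and variant cohorts with planted ground truth.

The generator emulates the statistical regime of the reviewed human
proteome — residue composition, a log-normal length distribution with a
mean near 560 residues, and an average sequon density near one per 118
residues — so that every pipeline stage can be exercised end-to-end
without any external download.  Variants are planted from the three LOG
rules (N lost, S/T lost, P introduced) and three GOG rules (N gained,
S/T gained, P removed), each verified against the rule-table classifier
at planting time so the recorded truth is consistent with the engine's
semantics rather than with the planting intent.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._alphabet import SLOT2_FORBIDDEN, STANDARD_AA, SWISSPROT_AA_FREQUENCIES
from .cohort import VariantCohort
from .engine import (
    ImpactCall,
    VariantRecord,
    classify_impact_rules,
    scan_sequence,
)
from .proteome import KnownSite, ProteinRecord, ProteomeSet

#: cancer Disease Ontology slim used as the default sampling palette;
#: 38 opaque term identifiers
DOID_PALETTE_38: tuple[str, ...] = (
    "DOID:0060119", "DOID:10283", "DOID:10534", "DOID:11054", "DOID:11934",
    "DOID:1115", "DOID:1240", "DOID:1319", "DOID:1324", "DOID:1612",
    "DOID:1781", "DOID:1793", "DOID:184", "DOID:1909", "DOID:1993",
    "DOID:219", "DOID:2174", "DOID:2394", "DOID:2531", "DOID:263",
    "DOID:2998", "DOID:3070", "DOID:3121", "DOID:3277", "DOID:3459",
    "DOID:3571", "DOID:363", "DOID:3953", "DOID:4159", "DOID:4362",
    "DOID:4607", "DOID:5041", "DOID:5672", "DOID:8618", "DOID:9256",
    "DOID:9538", "DOID:3565", "DOID:2994",
)

#: default distribution of the number of distinct cancer types per variant
DEFAULT_N_DOIDS_LAW: dict[int, float] = {
    1: 0.55, 2: 0.20, 3: 0.12, 4: 0.07, 5: 0.03, 6: 0.02, 7: 0.007, 8: 0.003,
}

#: default mixture over affected slots for planted LOG events; slot 2
#: (P introduction) is the rarest channel, as only one substitution type
#: can hit it
DEFAULT_LOG_SLOT_MIXTURE = (0.40, 0.15, 0.45)
DEFAULT_GOG_RULE_MIXTURE = {"n_gained": 0.45, "st_gained": 0.45, "p_lost": 0.10}

KEYWORD_POOL = ("Secreted", "Membrane", "Cytoplasm", "Nucleus")


class SimulationError(RuntimeError):
    """Requested synthetic configuration is infeasible."""


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic proteome/cohort bundle."""

    planted_sequons: dict[str, list[int]] = field(default_factory=dict)
    planted_variants: list[tuple[VariantRecord, str, int | None]] = field(
        default_factory=list
    )
    germline_overlap_keys: set[tuple[str, int, str, str]] = field(
        default_factory=set
    )
    doid_palette: tuple[str, ...] = DOID_PALETTE_38
    doid_weights: tuple[float, ...] | None = None


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of recovered impact calls against planted truth."""

    log_precision: float
    log_recall: float
    gog_precision: float
    gog_recall: float
    n_expected_log: int
    n_expected_gog: int


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def generate_proteome(
    n_proteins: int,
    length_law: tuple[float, float] = (560.0, 520.0),
    aa_frequencies: Mapping[str, float] | None = None,
    target_density: float = 1.0 / 118.0,
    seed: int = 0,
    signal_fraction: float = 0.17,
    keyword_fractions: Mapping[str, float] | None = None,
    min_length: int = 30,
    max_length: int = 8000,
) -> tuple[ProteomeSet, SyntheticTruth]:
    """Generate a proteome with a controlled overall sequon density.

    Sequences are drawn residue-wise from ``aa_frequencies`` (default:
    human background composition), then sequons are planted or ablated
    by local three-residue edits until the realized proteome-wide
    density matches ``target_density`` (default one sequon per 118
    residues) within 10%.  Signal peptides and cellular-component
    keywords are assigned to configurable fractions of proteins.
    Deterministic for a fixed seed.
    """
    if not 0.0 <= target_density <= 0.2:
        raise ValueError("target_density must lie in [0, 0.2]")
    freqs = dict(aa_frequencies or SWISSPROT_AA_FREQUENCIES)
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError("aa_frequencies must sum to 1 within 1e-9")
    letters = np.array(list(freqs))
    probs = np.array([freqs[a] for a in letters])
    if keyword_fractions is None:
        keyword_fractions = {
            "Secreted": 0.12, "Membrane": 0.30, "Cytoplasm": 0.35, "Nucleus": 0.30,
        }

    rng = np.random.default_rng(seed)
    mu, sigma = _lognormal_params(*length_law)
    lengths = np.clip(
        rng.lognormal(mu, sigma, size=n_proteins).astype(int), min_length, max_length
    )
    sequences = [
        list(rng.choice(letters, size=int(length), p=probs)) for length in lengths
    ]
    _tune_density(sequences, target_density, rng)

    truth = SyntheticTruth()
    proteome = ProteomeSet()
    for i, seq_list in enumerate(sequences):
        accession = f"SYN{i:05d}"
        sequence = "".join(seq_list)
        signal = None
        if rng.random() < signal_fraction:
            signal = (1, int(rng.integers(15, 31)))
        keywords = frozenset(
            kw for kw in KEYWORD_POOL if rng.random() < keyword_fractions.get(kw, 0.0)
        )
        proteome.add(
            ProteinRecord(
                accession=accession,
                sequence=sequence,
                signal_peptide=signal,
                keywords=keywords,
            )
        )
        truth.planted_sequons[accession] = scan_sequence(sequence)
    return proteome, truth


def _tune_density(
    sequences: list[list[str]], target_density: float, rng: np.random.Generator
) -> None:
    """Plant/ablate sequons in place until the pooled density hits target."""
    total_len = sum(len(s) for s in sequences)
    if total_len == 0:
        return
    counts = [len(scan_sequence("".join(s))) for s in sequences]
    target = round(target_density * total_len)
    weights = np.array([max(len(s) - 2, 0) for s in sequences], dtype=float)
    if weights.sum() == 0:
        if target > 0:
            raise SimulationError("sequences too short to hold any sequon")
        return
    weights /= weights.sum()
    max_attempts = 500 + 80 * abs(target - sum(counts))
    attempts = 0
    while sum(counts) != target:
        attempts += 1
        if attempts > max_attempts:
            break
        current = sum(counts)
        idx = int(rng.choice(len(sequences), p=weights))
        seq = sequences[idx]
        if len(seq) < 3:
            continue
        if current < target:
            pos = int(rng.integers(0, len(seq) - 2))
            saved = seq[pos : pos + 3]
            seq[pos] = "N"
            if seq[pos + 1] in SLOT2_FORBIDDEN:
                seq[pos + 1] = "A"
            if seq[pos + 2] not in "ST":
                seq[pos + 2] = "S" if rng.random() < 0.5 else "T"
        else:
            starts = scan_sequence("".join(seq))
            if not starts:
                continue
            pos = int(rng.choice(starts)) - 1
            saved = seq[pos : pos + 3]
            seq[pos] = str(rng.choice([a for a in "QLAGV"]))
        new_count = len(scan_sequence("".join(seq)))
        if abs((current - counts[idx] + new_count) - target) < abs(current - target):
            counts[idx] = new_count
        else:
            seq[pos : pos + 3] = saved
    realized = sum(counts) / total_len
    if target == 0:
        if sum(counts) != 0:
            raise SimulationError("could not ablate all sequons")
    elif not (0.9 * target_density <= realized <= 1.1 * target_density):
        raise SimulationError(
            f"could not reach target density {target_density:.5f}; "
            f"realized {realized:.5f}"
        )


def _sample_doids(
    rng: np.random.Generator,
    palette: Sequence[str],
    weights: Sequence[float] | None,
    n_doids_law: Mapping[int, float],
) -> frozenset[str]:
    ks = sorted(n_doids_law)
    ps = np.array([n_doids_law[k] for k in ks], dtype=float)
    ps /= ps.sum()
    k = int(rng.choice(ks, p=ps))
    k = min(k, len(palette))
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    chosen = rng.choice(len(palette), size=k, replace=False, p=w)
    return frozenset(palette[int(i)] for i in chosen)


def plant_variants(
    proteome: ProteomeSet,
    truth: SyntheticTruth,
    n_log: int = 50,
    n_gog: int = 50,
    n_neutral: int = 100,
    germline_fraction: float = 0.1,
    n_doids_law: Mapping[int, float] | None = None,
    seed: int = 0,
    log_slot_mixture: tuple[float, float, float] = DEFAULT_LOG_SLOT_MIXTURE,
) -> tuple[VariantCohort, VariantCohort, SyntheticTruth]:
    """Plant labeled LOG/GOG/neutral substitutions into a proteome.

    Every planted variant is validated with the rule-table classifier:
    LOG and GOG candidates must yield exactly the single expected call
    (compound events are rejected and redrawn) and neutral candidates
    must yield none.  A ``germline_fraction`` of somatic keys is
    duplicated into the germline cohort; those keys must vanish from the
    somatic-only subset.
    """
    rng = np.random.default_rng(seed)
    law = dict(n_doids_law or DEFAULT_N_DOIDS_LAW)
    planted: list[tuple[VariantRecord, str, int | None]] = []
    used_keys: set[tuple[str, int, str, str]] = set()

    def make_variant(acc: str, pos: int, ref: str, alt: str) -> VariantRecord:
        return VariantRecord(
            accession=acc,
            position=pos,
            ref_aa=ref,
            alt_aa=alt,
            origin="somatic",
            sources=frozenset({"sim"}),
            doids=_sample_doids(rng, truth.doid_palette, truth.doid_weights, law),
        )

    def verify_single(
        record: ProteinRecord, v: VariantRecord, effect: str, start: int
    ) -> bool:
        calls = classify_impact_rules(record, v)
        return len(calls) == 1 and calls[0].effect == effect and (
            calls[0].sequon_start == start
        )

    # --- LOG: pick sequons, hit one slot each ---------------------------
    sequon_pool = [
        (acc, start)
        for acc, starts in truth.planted_sequons.items()
        for start in starts
    ]
    rng.shuffle(sequon_pool)
    mixture = np.array(log_slot_mixture, dtype=float)
    mixture /= mixture.sum()
    non_n = [a for a in STANDARD_AA if a != "N"]
    non_st = [a for a in STANDARD_AA if a not in "ST"]
    n_log_planted = 0
    for acc, start in sequon_pool:
        if n_log_planted >= n_log:
            break
        record = proteome[acc]
        slot = int(rng.choice([1, 2, 3], p=mixture))
        for trial_slot in (slot, 1, 2, 3):
            pos = start + trial_slot - 1
            ref = record.residue(pos)
            if trial_slot == 1:
                alt = str(rng.choice(non_n))
            elif trial_slot == 2:
                alt = "P"
            else:
                alt = str(rng.choice(non_st))
            if ref == alt or ref not in STANDARD_AA:
                continue
            v = make_variant(acc, pos, ref, alt)
            if v.key in used_keys:
                continue
            if verify_single(record, v, "LOG", start):
                planted.append((v, "LOG", start))
                used_keys.add(v.key)
                n_log_planted += 1
                break
    if n_log_planted < n_log:
        raise SimulationError(
            f"could only plant {n_log_planted}/{n_log} LOG variants; "
            "increase proteome size or sequon density"
        )

    # --- GOG: enumerate creatable windows per rule ----------------------
    candidates: dict[str, list[tuple[str, int, str, int]]] = {
        "n_gained": [], "st_gained": [], "p_lost": [],
    }
    for record in proteome:
        seq = record.sequence
        for i in range(len(seq) - 2):  # i is 0-based window start
            a, b, c = seq[i], seq[i + 1], seq[i + 2]
            start = i + 1
            if a != "N" and a in STANDARD_AA and b not in SLOT2_FORBIDDEN and c in "ST":
                candidates["n_gained"].append((record.accession, start, a, start))
            if a == "N" and b == "P" and c in "ST":
                candidates["p_lost"].append((record.accession, start + 1, b, start))
            if (
                a == "N"
                and b not in SLOT2_FORBIDDEN
                and c not in "ST"
                and c in STANDARD_AA
            ):
                candidates["st_gained"].append((record.accession, start + 2, c, start))
    for pool in candidates.values():
        rng.shuffle(pool)
    rules = list(DEFAULT_GOG_RULE_MIXTURE)
    n_gog_planted = 0
    while n_gog_planted < n_gog:
        available = [r for r in rules if candidates[r]]
        if not available:
            raise SimulationError(
                f"could only plant {n_gog_planted}/{n_gog} GOG variants"
            )
        pa = np.array([DEFAULT_GOG_RULE_MIXTURE[r] for r in available])
        rule = str(rng.choice(available, p=pa / pa.sum()))
        acc, pos, ref, start = candidates[rule].pop()
        record = proteome[acc]
        if rule == "n_gained":
            alt = "N"
        elif rule == "p_lost":
            alt = str(rng.choice([a for a in STANDARD_AA if a != "P"]))
        else:
            alt = "S" if rng.random() < 0.5 else "T"
        if ref == alt:
            continue
        v = make_variant(acc, pos, ref, alt)
        if v.key in used_keys:
            continue
        if verify_single(record, v, "GOG", start):
            planted.append((v, "GOG", start))
            used_keys.add(v.key)
            n_gog_planted += 1

    # --- neutral ---------------------------------------------------------
    accs = sorted(proteome.records)
    n_neutral_planted = 0
    attempts = 0
    while n_neutral_planted < n_neutral:
        attempts += 1
        if attempts > 200 * max(n_neutral, 1):
            raise SimulationError(
                f"could only plant {n_neutral_planted}/{n_neutral} neutral variants"
            )
        acc = accs[int(rng.integers(0, len(accs)))]
        record = proteome[acc]
        pos = int(rng.integers(1, record.length + 1))
        ref = record.residue(pos)
        if ref not in STANDARD_AA:
            continue
        alt = str(rng.choice([a for a in STANDARD_AA if a != ref]))
        v = make_variant(acc, pos, ref, alt)
        if v.key in used_keys:
            continue
        if not classify_impact_rules(record, v):
            planted.append((v, "neutral", None))
            used_keys.add(v.key)
            n_neutral_planted += 1

    somatic = VariantCohort(
        variants=sorted((v for v, _, _ in planted), key=lambda v: v.key),
        origin_label="somatic",
    )

    # --- germline overlap ------------------------------------------------
    n_overlap = int(round(germline_fraction * len(somatic.variants)))
    overlap_idx = rng.choice(
        len(somatic.variants), size=n_overlap, replace=False
    ) if n_overlap else []
    germline_records = []
    overlap_keys: set[tuple[str, int, str, str]] = set()
    for i in sorted(int(j) for j in overlap_idx):
        sv = somatic.variants[i]
        overlap_keys.add(sv.key)
        germline_records.append(
            VariantRecord(
                accession=sv.accession,
                position=sv.position,
                ref_aa=sv.ref_aa,
                alt_aa=sv.alt_aa,
                origin="germline",
                sources=frozenset({"sim_germline"}),
                doids=frozenset(),
            )
        )
    germline = VariantCohort(variants=germline_records, origin_label="germline")

    truth.planted_variants = planted
    truth.germline_overlap_keys = overlap_keys
    return somatic, germline, truth


def sample_known_sites(
    proteome: ProteomeSet,
    truth: SyntheticTruth,
    fraction: float = 0.27,
    seed: int = 0,
) -> list[KnownSite]:
    """Mark a random fraction of sequons as database-annotated sites."""
    rng = np.random.default_rng(seed)
    sites: list[KnownSite] = []
    for acc in sorted(truth.planted_sequons):
        for start in truth.planted_sequons[acc]:
            if rng.random() < fraction:
                sites.append(
                    KnownSite(
                        accession=acc,
                        position=start,
                        evidence="experimental",
                        source="uniprot_ft",
                        atypical=False,
                    )
                )
    return sites


def truth_compare(
    calls: Sequence[ImpactCall], truth: SyntheticTruth
) -> RecoveryReport:
    """Precision/recall of calls against planted truth, per effect.

    The expected set is the planted LOG/GOG triples whose key is not in
    the germline overlap (the analysis target is the somatic-only
    subset).  Precision over an empty found set is reported as 1.0.
    """
    expected = {
        (v.key, eff, start)
        for v, eff, start in truth.planted_variants
        if eff in ("LOG", "GOG") and v.key not in truth.germline_overlap_keys
    }
    found = {(c.variant_key, c.effect, c.sequon_start) for c in calls}

    def _pr(effect: str) -> tuple[float, float, int]:
        exp = {t for t in expected if t[1] == effect}
        got = {t for t in found if t[1] == effect}
        tp = len(exp & got)
        precision = tp / len(got) if got else 1.0
        recall = tp / len(exp) if exp else 1.0
        return precision, recall, len(exp)

    lp, lr, nl = _pr("LOG")
    gp, gr, ng = _pr("GOG")
    return RecoveryReport(
        log_precision=lp,
        log_recall=lr,
        gog_precision=gp,
        gog_recall=gr,
        n_expected_log=nl,
        n_expected_gog=ng,
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize planted-variant truth as TSV."""
    with open(path, "w") as fh:
        fh.write("accession\tposition\tref\talt\texpected_effect\tsequon_start\n")
        for v, eff, start in sorted(truth.planted_variants, key=lambda t: t[0].key):
            fh.write(
                f"{v.accession}\t{v.position}\t{v.ref_aa}\t{v.alt_aa}\t"
                f"{eff}\t{start if start is not None else ''}\n"
            )
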
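"""Filters, rankings, spacing/density/occupancy summaries, binomial test."""

import math

import pytest

from sequonkit.engine import ImpactCall, VariantRecord
from sequonkit.proteome import KnownSite, ProteinRecord, ProteomeSet
from sequonkit.stats import (
    binomial_enrichment,
    cancer_count,
    density_per_protein,
    high_confidence_filter,
    multicancer_table,
    occupancy_stats,
    slot_distribution,
    spacing_stats,
    viability_filter,
)


def V(acc, pos, ref, alt, doids=()):
    return VariantRecord(
        accession=acc, position=pos, ref_aa=ref, alt_aa=alt, origin="somatic",
        doids=frozenset(doids),
    )


def call(acc, pos, ref, alt, effect, start):
    return ImpactCall(
        variant_key=(acc, pos, ref, alt), effect=effect, sequon_start=start,
        slot=pos - start + 1,
        rule={"LOG": {1: "n_lost", 2: "p_gained", 3: "st_lost"},
              "GOG": {1: "n_gained", 2: "p_lost", 3: "st_gained"}}[effect][
                  pos - start + 1],
    )


class TestCancerCount:
    def test_counts_distinct_doids(self):
        v = V("P10721", 486, "N", "D",
              doids={"DOID:184", "DOID:1993", "DOID:219", "DOID:5672"})
        assert cancer_count(v) == 4

    def test_empty_is_zero(self):
        assert cancer_count(V("P1", 5, "N", "D")) == 0

    def test_duplicates_collapse_by_set_semantics(self):
        v = V("P1", 5, "N", "D",
              doids=frozenset(["DOID:219", "DOID:219", "DOID:1324"]))
        assert cancer_count(v) == 2


class TestViability:
    def test_membrane_keyword_kept(self):
        p = ProteomeSet()
        p.add(ProteinRecord("P1", "MNVS", keywords=frozenset({"Membrane"})))
        assert viability_filter(p) == {"P1"}

    def test_cytoplasm_nucleus_without_signal_dropped(self):
        p = ProteomeSet()
        p.add(ProteinRecord("P1", "MNVS",
                            keywords=frozenset({"Cytoplasm", "Nucleus"})))
        assert viability_filter(p) == set()

    def test_signal_peptide_alone_kept(self):
        p = ProteomeSet()
        p.add(ProteinRecord("P1", "M" * 30, signal_peptide=(1, 20)))
        assert viability_filter(p) == {"P1"}


class TestHighConfidence:
    sites = [
        KnownSite("P1", 10, "experimental", "uniprot_ft"),
        KnownSite("P1", 50, "curated", "dbptm", atypical=True),
    ]

    def test_log_at_known_site_kept(self):
        calls = [call("P1", 10, "N", "D", "LOG", 10)]
        assert high_confidence_filter(calls, self.sites) == calls

    def test_log_at_unannotated_sequon_dropped(self):
        calls = [call("P1", 30, "N", "D", "LOG", 30)]
        assert high_confidence_filter(calls, self.sites) == []

    def test_gog_never_high_confidence(self):
        calls = [call("P1", 10, "D", "N", "GOG", 10)]
        assert high_confidence_filter(calls, self.sites) == []

    def test_atypical_sites_do_not_confer_confidence(self):
        calls = [call("P1", 50, "N", "D", "LOG", 50)]
        assert high_confidence_filter(calls, self.sites) == []


class TestMultiCancerTable:
    def _fixture(self):
        proteome = ProteomeSet()
        for acc in ("A1", "A2", "A3"):
            proteome.add(
                ProteinRecord(acc, "A" * 20 + "NAT" + "A" * 20,
                              keywords=frozenset({"Membrane"}))
            )
        proteome.add(ProteinRecord("A4", "A" * 20 + "NAT" + "A" * 20))  # not viable
        variants = [
            V("A1", 21, "N", "D", doids={"DOID:1", "DOID:2", "DOID:3", "DOID:4"}),
            V("A2", 21, "N", "D", doids={"DOID:1", "DOID:2", "DOID:3"}),
            V("A3", 21, "N", "D", doids={"DOID:1", "DOID:2"}),
            V("A4", 21, "N", "D", doids={"DOID:1", "DOID:2", "DOID:3"}),
        ]
        calls = [call(v.accession, 21, "N", "D", "LOG", 21) for v in variants]
        return proteome, variants, calls

    def test_filters_and_sorting(self):
        proteome, variants, calls = self._fixture()
        rows = multicancer_table(calls, variants, [], proteome, min_cancers=3)
        # A3 below threshold, A4 not viable
        assert [r.accession for r in rows] == ["A1", "A2"]
        assert rows[0].n_cancers == 4

    def test_monotone_in_min_cancers(self):
        proteome, variants, calls = self._fixture()
        previous = None
        for threshold in (1, 2, 3, 4, 5):
            rows = {
                r.variant_key
                for r in multicancer_table(
                    calls, variants, [], proteome, min_cancers=threshold
                )
            }
            if previous is not None:
                assert rows <= previous
            previous = rows

    def test_empty_calls_empty_table(self):
        proteome, variants, _ = self._fixture()
        assert multicancer_table([], variants, [], proteome) == []


class TestSpacing:
    def test_single_protein_gaps(self):
        s = spacing_stats({"P1": [10, 11, 130]})
        assert (s.minimum, s.maximum, s.mean) == (1, 119, 60.0)

    def test_no_gaps_is_none(self):
        assert spacing_stats({"P1": [5], "P2": [9]}) is None
        assert spacing_stats({}) is None

    def test_pooled_median_across_proteins(self):
        s = spacing_stats({"P1": [1, 2], "P2": [1, 4]})
        assert s.median == 2.0
        assert s.n_gaps == 2

    def test_gaps_at_least_one_and_sample_sd(self):
        s = spacing_stats({"P1": [1, 2, 3, 10]})
        assert s.minimum >= 1
        assert s.sd == pytest.approx(
            math.sqrt(((1 - 3) ** 2 + (1 - 3) ** 2 + (7 - 3) ** 2) / 2)
        )


class TestDensity:
    def _proteome(self, lengths):
        p = ProteomeSet()
        for acc, length in lengths.items():
            p.add(ProteinRecord(acc, "A" * length))
        return p

    def test_density_and_reciprocal(self):
        p = self._proteome({"P1": 100})
        (rec,) = density_per_protein({"P1": [1, 25, 50, 75]}, p)
        assert rec.density == pytest.approx(0.04)
        assert rec.residues_per_event == pytest.approx(25.0)
        assert rec.density * rec.residues_per_event == pytest.approx(1.0)

    def test_sialomucin_like_density(self):
        """Nine sequons on 197 residues: about one per 22 residues."""
        p = self._proteome({"CD164": 197})
        (rec,) = density_per_protein({"CD164": list(range(1, 180, 22))}, p)
        assert rec.residues_per_event == pytest.approx(21.9, abs=0.05)

    def test_zero_event_proteins_omitted_and_ranking(self):
        p = self._proteome({"P1": 100, "P2": 50, "P3": 80})
        records = density_per_protein(
            {"P1": [1, 2], "P2": [1, 2], "P3": []}, p
        )
        assert [r.accession for r in records] == ["P2", "P1"]
        assert all(0 < r.density <= 1 for r in records)


class TestSlotDistribution:
    def test_counts_and_total(self):
        calls = [
            call("P1", 10, "N", "D", "LOG", 10),
            call("P1", 22, "T", "A", "LOG", 20),
            call("P1", 32, "S", "A", "LOG", 30),
        ]
        table = slot_distribution(calls)
        assert table["LOG"] == {1: 1, 2: 0, 3: 2}
        assert sum(sum(v.values()) for v in table.values()) == len(calls)

    def test_empty_is_all_zero(self):
        table = slot_distribution([])
        assert all(n == 0 for eff in table.values() for n in eff.values())


def enumeration_pvalue(k, n, p0):
    """Independent exact oracle: sum point masses <= that of k."""
    pmf = [math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    threshold = pmf[k] * (1 + 1e-12)
    return min(1.0, sum(p for p in pmf if p <= threshold))


class TestBinomialEnrichment:
    @pytest.mark.parametrize(
        "k,n,p0,expected",
        [
            (7, 10, 0.5, 0.34375),
            (10, 10, 0.5, 2 / 1024),
            (5, 10, 0.5, 1.0),
        ],
    )
    def test_hand_enumerated_examples(self, k, n, p0, expected):
        assert binomial_enrichment(k, n, p0).p_value == pytest.approx(expected)

    def test_matches_enumeration_for_all_small_n(self):
        for n in range(1, 21):
            for p0 in (0.1, 0.3, 0.5, 0.8):
                for k in range(n + 1):
                    assert binomial_enrichment(k, n, p0).p_value == pytest.approx(
                        enumeration_pvalue(k, n, p0), rel=1e-9
                    ), (k, n, p0)

    def test_symmetry_at_half(self):
        for n in (5, 12, 20):
            for k in range(n + 1):
                assert binomial_enrichment(k, n, 0.5).p_value == pytest.approx(
                    binomial_enrichment(n - k, n, 0.5).p_value
                )

    @pytest.mark.parametrize("k,n,p0", [(5, 4, 0.5), (-1, 4, 0.5), (2, 4, 0.0), (2, 4, 1.0)])
    def test_invalid_inputs_rejected(self, k, n, p0):
        with pytest.raises(ValueError):
            binomial_enrichment(k, n, p0)


class TestOccupancy:
    def _proteome(self, n=10):
        p = ProteomeSet()
        for i in range(n):
            p.add(ProteinRecord(f"P{i}", "A" * 50))
        return p

    def test_fraction_with_sequon(self):
        p = self._proteome(10)
        lists = {f"P{i}": ([5] if i < 6 else []) for i in range(10)}
        summary = occupancy_stats(lists, [], p)
        assert summary.fraction_proteins_with_sequon == pytest.approx(0.6)

    def test_occupancy_ratio(self):
        p = self._proteome(2)
        lists = {"P0": [1, 5, 9, 13], "P1": [1, 5, 9, 13]}
        sites = [
            KnownSite("P0", 1, "experimental", "uniprot_ft"),
            KnownSite("P0", 5, "experimental", "uniprot_ft"),
        ]
        summary = occupancy_stats(lists, sites, p)
        assert summary.occupancy == pytest.approx(2 / 8)
        # glycoprotein view: only P0 carries known sites
        assert summary.glycoprotein_occupancy == pytest.approx(2 / 4)

    def test_atypical_sites_excluded(self):
        p = self._proteome(1)
        sites = [KnownSite("P0", 1, "experimental", "uniprot_ft", atypical=True)]
        summary = occupancy_stats({"P0": [1, 5]}, sites, p)
        assert summary.occupancy == 0.0
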
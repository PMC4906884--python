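"""Filter cascade: private filter, region filter, functional classes,
candidate-gene intersection, segregation check."""

import pytest

import mosaiclink as ml
from mosaiclink import filtering
from mosaiclink.filtering import CohortIndex, VariantRecord
from mosaiclink.genome import GenomicInterval
from mosaiclink.pedigree import FEMALE, MALE, Individual, Pedigree
from mosaiclink.splice import build_gene


def _rec(chrom="1", pos=100, ref="G", alt="A"):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt)


EMPTY = CohortIndex.from_keys([])


class TestFilterPrivate:
    def test_cohort_presence_removes(self):
        rec = _rec()
        local = CohortIndex.from_keys([rec.key])
        assert ml.filtering.filter_private([rec], local, EMPTY) == []
        assert ml.filtering.filter_private([rec], EMPTY, local) == []

    def test_absent_from_both_retained_in_order(self):
        recs = [_rec(pos=p) for p in (5, 3, 9)]
        assert ml.filtering.filter_private(recs, EMPTY, EMPTY) == recs

    def test_different_alt_at_known_site_is_still_private(self):
        rec = _rec(alt="T")
        local = CohortIndex.from_keys([("1", 100, "G", "A")])
        assert ml.filtering.filter_private([rec], local, EMPTY) == [rec]

    def test_generated_partition_is_exact(self, case_records, cohort_indexes, sim_bundle):
        local, global_ = cohort_indexes
        p = sim_bundle["params"]
        survivors = ml.filtering.filter_private(case_records, local, global_)
        assert len(survivors) == p.n_private_variants == 100


class TestFilterByRegions:
    REGIONS = [GenomicInterval("1", 100, 200)]

    @pytest.mark.parametrize(
        "pos,kept", [(100, True), (200, True), (201, False), (99, False)]
    )
    def test_inclusive_boundaries(self, pos, kept):
        out, _ = ml.filtering.filter_by_regions([_rec(pos=pos)], self.REGIONS)
        assert bool(out) is kept

    def test_idempotent(self, case_records, sim_bundle):
        regions = sim_bundle["regions"]
        once, frac1 = ml.filtering.filter_by_regions(case_records, regions)
        twice, frac2 = ml.filtering.filter_by_regions(once, regions)
        assert [r.key for r in twice] == [r.key for r in once]
        assert frac2 == 0.0

    def test_empty_region_list_excludes_all(self):
        out, frac = ml.filtering.filter_by_regions([_rec()], [])
        assert out == [] and frac == 1.0

    def test_display_percent_paper_funnel(self):
        assert ml.excluded_percent(6054, 785) == 87


class TestClassifyFunctional:
    GENE = build_gene("G1", "1", "+", 1000, [100, 50], intron_length=200)

    @pytest.mark.parametrize(
        "pos,expected",
        [
            (1050, "coding"),  # inside exon 1
            (1100, "splice_site"),  # intron position +1
            (1101, "splice_site"),  # intron position +2
            (1102, "other"),  # +3: deep intron
            (1298, "splice_site"),  # acceptor -2
            (1299, "splice_site"),  # acceptor -1
            (500, "other"),  # intergenic
        ],
    )
    def test_classes(self, pos, expected):
        rec = _rec(pos=pos)
        ml.filtering.classify_functional([rec], [self.GENE])
        assert rec.functional_class == expected

    def test_chromosome_without_genes_is_other(self):
        rec = _rec(chrom="9", pos=1050)
        counts = ml.filtering.classify_functional([rec], [self.GENE])
        assert rec.functional_class == "other"
        assert counts == {"coding": 0, "splice_site": 0, "other": 1}


class TestCandidateGenes:
    COORDS = {
        "A": GenomicInterval("1", 100, 200),
        "B": GenomicInterval("1", 300, 400),
        "C": GenomicInterval("2", 100, 200),
    }

    def test_overlap_rule(self):
        regions = [GenomicInterval("1", 150, 300)]  # A inside, B 1bp overlap
        got = ml.filtering.candidate_genes_in_regions(
            ["A", "B", "C"], self.COORDS, regions
        )
        assert got == ["A", "B"]

    def test_missing_coordinates_excluded(self):
        got = ml.filtering.candidate_genes_in_regions(
            ["A", "Z"], self.COORDS, [GenomicInterval("1", 1, 1000)]
        )
        assert got == ["A"]


class TestRunCascade:
    def test_unique_causal_survivor(self, case_records, cohort_indexes, sim_bundle):
        local, global_ = cohort_indexes
        vsim = sim_bundle["vsim"]
        res = ml.run_cascade(
            case_records,
            local,
            global_,
            sim_bundle["regions"],
            vsim.candidate_gene_names,
            vsim.genes,
        )
        assert [r.var_id for r in res.survivors] == [vsim.truth.causal_variant_id]
        counts = res.counts
        funnel = [
            counts["input"],
            counts["private"],
            counts["in_region"],
            counts["splice_in_candidate"],
        ]
        assert funnel == sorted(funnel, reverse=True)

    def test_counts_monotone_and_subsets(self, case_records, cohort_indexes, sim_bundle):
        local, global_ = cohort_indexes
        vsim = sim_bundle["vsim"]
        res = ml.run_cascade(
            case_records, local, global_, sim_bundle["regions"],
            vsim.candidate_gene_names, vsim.genes,
        )
        private = ml.filtering.filter_private(case_records, local, global_)
        in_region, _ = ml.filtering.filter_by_regions(private, sim_bundle["regions"])
        assert {r.key for r in res.survivors} <= {r.key for r in in_region}
        assert {r.key for r in in_region} <= {r.key for r in private}

    def test_empty_case_input_emits_zero_counts(self, cohort_indexes, sim_bundle):
        local, global_ = cohort_indexes
        vsim = sim_bundle["vsim"]
        res = ml.run_cascade(
            [], local, global_, sim_bundle["regions"],
            vsim.candidate_gene_names, vsim.genes,
        )
        assert res.survivors == []
        assert set(res.counts.values()) == {0}


class TestSegregation:
    def _ped(self, n=5):
        members = [Individual("SIRE", None, None, MALE, False)]
        for i in range(n):
            members.append(Individual(f"D{i}", None, None, FEMALE, False))
            members.append(Individual(f"C{i}", "SIRE", f"D{i}", MALE, True))
        return Pedigree(members)

    def test_mosaic_sire_passes(self):
        ped = self._ped()
        calls = {f"C{i}": "0/1" for i in range(5)}
        calls.update({f"D{i}": "0/0" for i in range(5)})
        calls["SIRE"] = 0.15
        report = ml.segregation_check(calls, ped)
        assert report.passed

    def test_carrier_dam_fails(self):
        ped = self._ped()
        calls = {f"C{i}": "0/1" for i in range(5)}
        calls.update({f"D{i}": "0/0" for i in range(5)})
        calls["D2"] = "0/1"
        calls["SIRE"] = 0.15
        assert not ml.segregation_check(calls, ped).passed

    def test_homozygous_case_fails(self):
        ped = self._ped()
        calls = {f"C{i}": "0/1" for i in range(5)}
        calls["C0"] = "1/1"
        calls.update({f"D{i}": "0/0" for i in range(5)})
        calls["SIRE"] = 0.15
        assert not ml.segregation_check(calls, ped).passed

    def test_untyped_individuals_flagged_not_failed(self):
        ped = self._ped()
        calls = {f"C{i}": "0/1" for i in range(5)}
        calls.update({f"D{i}": "0/0" for i in range(4)})
        calls["SIRE"] = "0/1"
        report = ml.segregation_check(calls, ped)
        assert report.passed and report.untyped == ["D4"]
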
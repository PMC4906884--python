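"""Generator contracts: pedigree transmission, gene dropping, variant
partition, allelic depths, gestation records, determinism."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
import scipy.stats

import mosaiclink as ml
from mosaiclink import io, simulate
from mosaiclink.exceptions import DomainError, InvalidDesignError
from mosaiclink.genome import ALLELE_B, MISSING


def _small(seed=0, **kw):
    base = dict(
        n_offspring=12,
        n_chromosomes=2,
        markers_per_chromosome=30,
        chromosome_length=4_000_000,
        causal_chromosome=1,
        causal_pos=2_000_000,
        cosegregation_window=300_000,
        seed=seed,
    )
    base.update(kw)
    return ml.SimParams(**base)


class TestPedigree:
    @pytest.mark.parametrize(
        "fraction,expected", [(1.0, 4), (0.0, 0)]
    )
    def test_certain_and_impossible_transmission(self, fraction, expected):
        p = _small(n_offspring=4, mosaic_fraction_germline=fraction)
        ped = ml.simulate_pedigree(p)
        assert len(ped.affected()) == expected

    def test_affected_count_within_binomial_interval(self):
        # central 99.9% interval of Binomial(515, 0.15), computed from the CDF
        lo = scipy.stats.binom.ppf(0.0005, 515, 0.15)
        hi = scipy.stats.binom.ppf(0.9995, 515, 0.15)
        p = _small(n_offspring=515, mosaic_fraction_germline=0.15, seed=11)
        n_aff = len(ml.simulate_pedigree(p).affected())
        assert lo <= n_aff <= hi

    def test_affection_equals_transmission_flag(self):
        ped = ml.simulate_pedigree(_small(seed=3))
        flags = simulate.transmitted_flags(ped)
        for ind in ped:
            if ind.sire_id == simulate.SIRE_ID:
                assert flags[ind.id] == ind.affected

    def test_single_offspring_rejected(self):
        with pytest.raises(InvalidDesignError):
            ml.simulate_pedigree(_small(n_offspring=1))

    def test_structure_one_sire_one_dam_each(self):
        ped = ml.simulate_pedigree(_small())
        offspring = [i for i in ped if i.sire_id is not None]
        assert {i.sire_id for i in offspring} == {simulate.SIRE_ID}
        assert len({i.dam_id for i in offspring}) == len(offspring)


class TestMarkerGenotypes:
    def test_mendelian_consistency_every_offspring_every_marker(self):
        p = _small(seed=5)
        ped = ml.simulate_pedigree(p)
        geno, mmap = ml.simulate_marker_genotypes(ped, p)
        for ind in ped:
            if ind.sire_id is None:
                continue
            child = geno.alleles[geno.row(ind.id)]
            sire = geno.alleles[geno.row(ind.sire_id)]
            dam = geno.alleles[geno.row(ind.dam_id)]
            assert all(child[j, 0] in sire[j] for j in range(len(mmap)))
            assert all(child[j, 1] in dam[j] for j in range(len(mmap)))

    def test_causal_window_cosegregates_with_affection(self):
        p = _small(seed=6)
        ped = ml.simulate_pedigree(p)
        geno, mmap = ml.simulate_marker_genotypes(ped, p)
        idx = mmap.indices(str(p.causal_chromosome))
        pos = mmap.df["pos"].to_numpy()
        window = idx[np.abs(pos[idx] - p.causal_pos) <= p.cosegregation_window]
        assert window.size > 0
        for ind in ped:
            if ind.sire_id is None:
                continue
            paternal = geno.alleles[geno.row(ind.id), window, 0]
            expected = ALLELE_B if ind.affected else 0
            assert (paternal == expected).all()

    def test_founder_heterozygosity_matches_maf(self):
        p = _small(seed=7, marker_maf=0.5, n_offspring=40,
                   markers_per_chromosome=100)
        ped = ml.simulate_pedigree(p)
        geno, mmap = ml.simulate_marker_genotypes(ped, p)
        idx = mmap.indices(str(p.causal_chromosome))
        pos = mmap.df["pos"].to_numpy()
        window = set(
            idx[np.abs(pos[idx] - p.causal_pos) <= p.cosegregation_window]
        )
        keep = [j for j in range(len(mmap)) if j not in window]
        founders = [i.id for i in ped.founders()]
        rows = [geno.row(i) for i in founders]
        sub = geno.alleles[np.ix_(rows, keep)]
        het = (sub[:, :, 0] != sub[:, :, 1]).mean()
        # expected 2*maf*(1-maf) = 0.5; generous sampling tolerance
        assert het == pytest.approx(0.5, abs=0.02)

    def test_no_missing_calls(self):
        p = _small(seed=8)
        ped = ml.simulate_pedigree(p)
        geno, _ = ml.simulate_marker_genotypes(ped, p)
        assert not (geno.alleles == MISSING).any()


class TestVariantCohorts:
    def test_in_region_count_forced_by_rounding(self, sim_bundle):
        vsim = sim_bundle["vsim"]
        p = sim_bundle["params"]
        regions = sim_bundle["regions"]
        in_region = [
            v
            for v in vsim.case_variants
            if any(r.contains(v.chrom, v.pos) for r in regions)
            and v.key not in vsim.local_index
            and v.key not in vsim.global_index
        ]
        expected = simulate.round_half_away(
            p.n_private_variants * p.private_in_region_fraction
        )
        assert len(in_region) == expected == 13

    def test_private_shared_partition_exact(self, sim_bundle):
        vsim = sim_bundle["vsim"]
        p = sim_bundle["params"]
        shared = [
            v
            for v in vsim.case_variants
            if v.key in vsim.local_index or v.key in vsim.global_index
        ]
        assert len(shared) == p.n_cohort_shared_variants
        assert len(vsim.case_variants) - len(shared) == p.n_private_variants

    def test_planted_donor_variant_is_gt_to_at(self, sim_bundle):
        vsim = sim_bundle["vsim"]
        causal = next(
            v for v in vsim.case_variants if v.var_id == vsim.truth.causal_variant_id
        )
        assert (causal.ref, causal.alt) == ("G", "A")
        dinuc = vsim.reference.fetch(causal.chrom, causal.pos, causal.pos + 1)
        assert dinuc == "GT"

    def test_empty_regions_rejected(self):
        with pytest.raises(InvalidDesignError):
            ml.simulate_variant_cohorts(_small(), [])

    def test_candidate_gene_count(self, sim_bundle):
        vsim = sim_bundle["vsim"]
        p = sim_bundle["params"]
        assert len(vsim.candidate_gene_names) == p.n_candidate_genes_total


class TestAllelicDepths:
    @pytest.mark.parametrize("fraction,expected", [(0.0, 0), (1.0, 200)])
    def test_degenerate_fractions(self, fraction, expected):
        t = ml.simulate_allelic_depths(fraction, 200, 5, seed=0)
        assert (t["mutant_count"] == expected).all()

    def test_pooled_fraction_within_binomial_interval(self):
        t = ml.simulate_allelic_depths(0.15, 1000, 50, seed=4)
        pooled = t["mutant_count"].sum() / t["total_count"].sum()
        n = 1000 * 50
        lo = scipy.stats.binom.ppf(0.0005, n, 0.15) / n
        hi = scipy.stats.binom.ppf(0.9995, n, 0.15) / n
        assert lo <= pooled <= hi

    def test_fraction_domain_checked(self):
        with pytest.raises(DomainError):
            ml.simulate_allelic_depths(1.5, 100, 5, seed=0)


class TestGestation:
    def test_zero_sd_gives_exact_means(self):
        p = _small(seed=9, gestation_sd=0.0, mosaic_fraction_germline=0.5)
        ped = ml.simulate_pedigree(p)
        t = ml.simulate_gestation_records(p, ped)
        normal = t.loc[t.status == "normal", "gestation_days"]
        affected = t.loc[t.status == "affected", "gestation_days"]
        assert (normal == p.gestation_mean_normal).all()
        assert (affected == p.gestation_mean_affected).all()

    def test_truncation_bounds_respected(self):
        p = _small(seed=10, n_offspring=200, gestation_sd=20.0,
                   mosaic_fraction_germline=0.5)
        ped = ml.simulate_pedigree(p)
        t = ml.simulate_gestation_records(p, ped)
        lo, hi = p.gestation_bounds
        assert t["gestation_days"].between(lo, hi).all()

    def test_mean_difference_recovered(self):
        p = _small(seed=12, n_offspring=400, mosaic_fraction_germline=0.5)
        ped = ml.simulate_pedigree(p)
        t = ml.simulate_gestation_records(p, ped)
        diff = (
            t.loc[t.status == "normal", "gestation_days"].mean()
            - t.loc[t.status == "affected", "gestation_days"].mean()
        )
        se = 3 * p.gestation_sd / np.sqrt(150)
        assert diff == pytest.approx(
            p.gestation_mean_normal - p.gestation_mean_affected, abs=se
        )


class TestDeterminism:
    def test_fixed_seed_byte_identical_outputs(self, tmp_path):
        digests = []
        for run in ("a", "b"):
            p = _small(seed=77)
            ped = ml.simulate_pedigree(p)
            geno, mmap = ml.simulate_marker_genotypes(ped, p)
            regions = simulate.true_regions(p)
            vsim = ml.simulate_variant_cohorts(p, regions)
            out = tmp_path / run
            out.mkdir()
            io.write_ped_map(out / "sim", ped, geno, mmap)
            from mosaiclink.filtering import VariantRecord

            io.write_vcf(
                out / "case.vcf",
                [VariantRecord.from_case_variant(v) for v in vsim.case_variants],
                {str(c): p.chromosome_length for c in range(1, p.n_chromosomes + 1)},
            )
            io.write_gff3(out / "genes.gff3", vsim.genes)
            h = hashlib.sha256()
            for f in sorted(out.iterdir()):
                h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]
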
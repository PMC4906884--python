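"""Allele-sharing linkage: transmission deduction, S-pairs, exact null
moments vs enumeration, Kong-Cox LOD, region merging, scan behaviour."""

import itertools
from math import comb, log10

import numpy as np
import pandas as pd
import pytest

import mosaiclink as ml
from mosaiclink import linkage
from mosaiclink.exceptions import UndefinedStatisticError
from mosaiclink.genome import GenotypeMatrix, MarkerMap
from mosaiclink.linkage import Transmission
from mosaiclink.pedigree import FEMALE, MALE, Individual, Pedigree


def _trio_matrix(sire, dam, child):
    """One-marker genotype matrix for a sire-dam-child trio."""
    ped = Pedigree(
        [
            Individual("S", None, None, MALE, False),
            Individual("D", None, None, FEMALE, False),
            Individual("C", "S", "D", MALE, True),
        ]
    )
    alleles = np.array([[sire], [dam], [child]], dtype=np.int8)
    return GenotypeMatrix(["S", "D", "C"], alleles), ped


class TestTransmissionInference:
    @pytest.mark.parametrize(
        "sire,dam,child,expected",
        [
            # sire AB, dam AA, child AB -> paternal allele must be B
            ((0, 1), (0, 0), (0, 1), Transmission.ALLELE_B),
            # all heterozygous: both assignments compatible
            ((0, 1), (0, 1), (0, 1), Transmission.AMBIGUOUS),
            # homozygous sire carries no sharing information
            ((0, 0), (0, 1), (0, 0), Transmission.UNINFORMATIVE),
            # child hom-ref with hom-alt dam is impossible
            ((0, 1), (1, 1), (0, 0), Transmission.INCONSISTENT),
            # forced deductions from homozygous children
            ((0, 1), (0, 1), (0, 0), Transmission.ALLELE_A),
            ((0, 1), (0, 1), (1, 1), Transmission.ALLELE_B),
        ],
    )
    def test_deduction_rules(self, sire, dam, child, expected):
        geno, ped = _trio_matrix(sire, dam, child)
        result = ml.linkage.infer_sire_transmission(geno, ped, 0, sire_id="S")
        assert result["C"] == expected


class TestSpairs:
    @pytest.mark.parametrize(
        "transmissions,expected",
        [
            ([1, 1, 1, 1], 6),  # all share: C(4,2)
            ([0, 0, 1, 1], 2),
            ([0, 1], 0),
        ],
    )
    def test_pair_counts(self, transmissions, expected):
        assert ml.spairs(transmissions) == expected

    def test_label_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ts = rng.integers(0, 2, size=int(rng.integers(2, 10)))
            assert ml.spairs(ts) == ml.spairs(1 - ts)

    def test_too_few_informative(self):
        with pytest.raises(UndefinedStatisticError):
            ml.spairs([1])


class TestNullMoments:
    @pytest.mark.parametrize("n,mean,var", [(2, 0.5, 0.25), (4, 3.0, 1.5)])
    def test_small_n_frozen_values(self, n, mean, var):
        assert ml.spairs_null_moments(n) == (mean, var)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_closed_form_equals_full_enumeration(self, n):
        """Oracle: brute-force all 2^n transmission vectors."""
        values = []
        for vec in itertools.product((0, 1), repeat=n):
            k = sum(vec)
            values.append(comb(k, 2) + comb(n - k, 2))
        values = np.array(values, dtype=float)
        mean, var = ml.spairs_null_moments(n)
        assert mean == pytest.approx(values.mean(), rel=1e-12)
        assert var == pytest.approx(values.var(), rel=1e-12)

    @pytest.mark.parametrize("n", range(2, 13))
    def test_mean_is_half_pair_count(self, n):
        mean, _ = ml.spairs_null_moments(n)
        assert mean == pytest.approx(comb(n, 2) / 2)


class TestZscoreAndLod:
    @pytest.mark.parametrize(
        "s,n,expected",
        [(6, 4, (6 - 3) / 1.5**0.5), (3, 4, 0.0), (0, 2, -1.0)],
    )
    def test_zscore(self, s, n, expected):
        assert ml.npl_zscore(s, n) == pytest.approx(expected)

    @pytest.mark.parametrize("z", [0.0, -0.5, -3.0])
    def test_lod_zero_without_sharing_excess(self, z):
        assert ml.kong_cox_lod([z]) == 0.0

    def test_lod_at_delta_cap(self):
        # l(delta) = 2 ln(1 + delta) increasing on [0, 1]: max at boundary
        assert ml.kong_cox_lod([1.0, 1.0], delta_cap=1.0) == pytest.approx(
            2 * log10(2)
        )

    def test_lod_interior_maximum_matches_grid_search(self):
        zs = [2.0, -0.8, 1.5]
        d_max = min(1.0, -1.0 / -0.8 * (1 - 1e-12))
        grid = np.linspace(0, d_max, 200_001)[:-1]
        ll = np.log1p(np.outer(grid, zs)).sum(axis=1)
        assert ml.kong_cox_lod(zs) == pytest.approx(
            ll.max() / np.log(10), abs=1e-6
        )

    def test_lod_family_order_invariant(self):
        zs = [1.2, -0.3, 0.7, 2.1]
        assert ml.kong_cox_lod(zs) == pytest.approx(ml.kong_cox_lod(zs[::-1]))


class TestMergeRegions:
    def _map(self, n, chrom="1"):
        return MarkerMap(
            pd.DataFrame(
                {
                    "marker": [f"m{i}" for i in range(n)],
                    "chrom": chrom,
                    "pos": [100 * (i + 1) for i in range(n)],
                }
            )
        )

    @pytest.mark.parametrize(
        "flags,gap,expected",
        [
            ([1, 1, 1, 0, 0], 0, [("1", 100, 300)]),
            ([1, 0, 1], 1, [("1", 100, 300)]),
            ([1, 0, 1], 0, [("1", 100, 100), ("1", 300, 300)]),
            ([0, 0, 0], 0, []),
        ],
    )
    def test_runs_and_gap_bridging(self, flags, gap, expected):
        got = ml.merge_regions(flags, self._map(len(flags)), gap_tolerance=gap)
        assert [(r.chrom, r.start, r.end) for r in got] == expected


class TestGenomeScan:
    def test_causal_region_found(self, sim_bundle):
        scan = ml.genome_scan(
            sim_bundle["genotypes"],
            sim_bundle["pedigree"],
            sim_bundle["map"],
            n_permutations=500,
            seed=1,
        )
        p = sim_bundle["params"]
        assert any(
            r.contains(str(p.causal_chromosome), p.causal_pos)
            for r in scan.significant_regions
        )

    def test_null_z_standardised(self):
        """Across many unlinked null markers the z scores have mean ~0 and
        variance ~1."""
        p = ml.SimParams(
            seed=42, n_offspring=24, mosaic_fraction_germline=1.0,
            n_chromosomes=2, markers_per_chromosome=400,
            recombination_rate=0.5, cosegregation_window=0,
            causal_chromosome=1, causal_pos=5_000_000,
        )
        ped = ml.simulate_pedigree(p)
        geno, mmap = ml.simulate_marker_genotypes(ped, p)
        scan = ml.genome_scan(geno, ped, mmap, n_permutations=100, seed=42)
        z = scan.table["z"].dropna()
        assert z.mean() == pytest.approx(0.0, abs=0.1)
        assert z.var() == pytest.approx(1.0, abs=0.15)

    def test_single_case_rejected(self):
        p = ml.SimParams(seed=2, n_offspring=2, mosaic_fraction_germline=0.0)
        ped = ml.simulate_pedigree(p)
        geno, mmap = ml.simulate_marker_genotypes(ped, p)
        with pytest.raises(UndefinedStatisticError):
            ml.genome_scan(geno, ped, mmap, n_permutations=100, seed=2)

    def test_scan_reports_informativeness(self, sim_bundle):
        scan = ml.genome_scan(
            sim_bundle["genotypes"],
            sim_bundle["pedigree"],
            sim_bundle["map"],
            n_permutations=100,
            seed=1,
        )
        n_aff = len(sim_bundle["pedigree"].affected())
        t = scan.table
        assert (t["n_informative"] <= n_aff).all()
        ok = t["n_informative"] >= 2
        assert t.loc[ok, "S"].notna().all()
        assert t.loc[~ok, "z"].isna().all()
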
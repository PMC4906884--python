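"""Synthetic-data generator for the whole pipeline.

Emulates the study design in which a phenotypically normal AI sire who is a
gonadal + somatic mosaic for a fully penetrant dominant lethal allele
produces a burst of malformed calves across many herds:

* a paternal half-sib pedigree (one sire, many dams, one calf each) where
  each calf inherits the mutant sire allele with probability equal to the
  germline mosaic fraction and is affected iff it does (full penetrance);
* BovineHD-like biallelic SNP array genotypes dropped through the pedigree
  by Mendelian gene dropping with recombination, with guaranteed
  co-segregation of the sire haplotype around the causal locus;
* a case whole-genome variant set containing cohort-shared variants,
  case-private variants inside and outside the linked regions, coding
  variants, and exactly one planted splice-donor G>A inside a candidate
  gene — plus local/global control-cohort variant indexes;
* binomially sampled mutant-allele depths per tissue (peak-area ratios of
  Sanger traces modelled as counts at an effective depth);
* gestation lengths for normal vs. affected calvings.

Every knob lives on :class:`SimParams`; a fixed seed makes all outputs
byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import DomainError, InvalidDesignError
from .genome import (
    ALLELE_A,
    ALLELE_B,
    GenomicInterval,
    GenotypeMatrix,
    MarkerMap,
    RegionReference,
)
from .pedigree import FEMALE, MALE, Individual, Pedigree
from .splice import GeneModel, build_gene, patch_splice_sites

# Distinct RNG streams per operation so ops are independently reproducible.
_STREAM_PEDIGREE = 1
_STREAM_GENOTYPES = 2
_STREAM_VARIANTS = 3
_STREAM_DEPTHS = 4
_STREAM_GESTATION = 5


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (deterministic count
    derivation; Python's banker's rounding would make .5 cases depend on
    parity)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SimParams:
    """Generative knobs for the synthetic study.

    Defaults encode the study conditions: germline mosaic fraction 0.15 and
    somatic (blood) fraction 0.05; gestation means 280.2 d (normal) vs
    276.2 d (affected); a ~13% in-region private-variant fraction mirroring
    the genome-wide funnel; 9 of 95 candidate genes inside linked regions.
    The toy genome is 10 chromosomes x 10 Mb with 200 evenly spaced markers
    per chromosome.
    """

    n_offspring: int = 120
    mosaic_fraction_germline: float = 0.15
    mosaic_fraction_soma: float = 0.05
    n_chromosomes: int = 10
    markers_per_chromosome: int = 200
    marker_maf: float = 0.3
    chromosome_length: int = 10_000_000
    causal_chromosome: int = 5
    causal_pos: int = 3_200_000
    cosegregation_window: int = 500_000
    recombination_rate: float = 0.01
    n_cohort_shared_variants: int = 900
    n_private_variants: int = 100
    private_in_region_fraction: float = 0.13
    coding_fraction: float = 0.15
    n_candidate_genes: int = 9
    n_candidate_genes_total: int = 95
    gestation_mean_normal: float = 280.2
    gestation_mean_affected: float = 276.2
    gestation_sd: float = 5.0
    gestation_bounds: tuple[float, float] = (240.0, 300.0)
    seed: int = 0

    def validation_errors(self) -> list[str]:
        """All violations, not just the first (used by config validation)."""
        errs = []
        for name in (
            "mosaic_fraction_germline",
            "mosaic_fraction_soma",
            "marker_maf",
            "private_in_region_fraction",
            "coding_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v} outside [0, 1]")
        for name in (
            "n_offspring",
            "n_chromosomes",
            "markers_per_chromosome",
            "chromosome_length",
            "n_candidate_genes",
        ):
            if getattr(self, name) <= 0:
                errs.append(f"{name}={getattr(self, name)} must be positive")
        for name in ("n_cohort_shared_variants", "n_private_variants"):
            if getattr(self, name) < 0:
                errs.append(f"{name}={getattr(self, name)} must be non-negative")
        if not 0.0 <= self.recombination_rate <= 0.5:
            errs.append(f"recombination_rate={self.recombination_rate} outside [0, 0.5]")
        if not 1 <= self.causal_chromosome <= self.n_chromosomes:
            errs.append(
                f"causal_chromosome={self.causal_chromosome} outside "
                f"1..{self.n_chromosomes}"
            )
        if not 1 <= self.causal_pos <= self.chromosome_length:
            errs.append(f"causal_pos={self.causal_pos} outside chromosome")
        if self.gestation_sd < 0:
            errs.append(f"gestation_sd={self.gestation_sd} must be >= 0")
        if self.n_candidate_genes_total < self.n_candidate_genes:
            errs.append("n_candidate_genes_total < n_candidate_genes")
        return errs

    def validate(self) -> None:
        errs = self.validation_errors()
        if errs:
            raise DomainError("; ".join(errs))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    causal_variant_id: Optional[str] = None
    transmitted_flags: dict[str, bool] = field(default_factory=dict)
    true_linked_regions: list[GenomicInterval] = field(default_factory=list)
    true_allele_fractions: dict[str, float] = field(default_factory=dict)


SIRE_ID = "SIRE"


def true_regions(params: SimParams) -> list[GenomicInterval]:
    """The co-segregation window around the causal locus — the region the
    linkage stage should rediscover."""
    chrom = str(params.causal_chromosome)
    lo = max(1, params.causal_pos - params.cosegregation_window)
    hi = min(params.chromosome_length, params.causal_pos + params.cosegregation_window)
    return [GenomicInterval(chrom, lo, hi)]


# ---------------------------------------------------------------------------
# Pedigree


def simulate_pedigree(params: SimParams) -> Pedigree:
    """One sire x ``n_offspring`` dams, one calf each.

    Each calf receives the mutant sire allele with probability
    ``mosaic_fraction_germline`` and is affected iff it does. Affection
    status therefore *is* the transmission flag (full penetrance).
    """
    params.validate()
    if params.n_offspring < 2:
        raise InvalidDesignError(
            "n_offspring must be >= 2: pair-sharing statistics are undefined "
            "for fewer than two half-sibs"
        )
    rng = params.rng(_STREAM_PEDIGREE)
    transmitted = rng.random(params.n_offspring) < params.mosaic_fraction_germline
    members = [Individual(SIRE_ID, None, None, MALE, False)]
    for i in range(params.n_offspring):
        dam = f"DAM{i + 1:04d}"
        calf = f"CALF{i + 1:04d}"
        members.append(Individual(dam, None, None, FEMALE, False))
        sex = MALE if rng.random() < 0.5 else FEMALE
        members.append(Individual(calf, SIRE_ID, dam, sex, bool(transmitted[i])))
    return Pedigree(members)


def transmitted_flags(pedigree: Pedigree) -> dict[str, bool]:
    """Per-offspring mutant-transmission flags (== affection status under
    full penetrance)."""
    return {
        ind.id: ind.affected for ind in pedigree if ind.sire_id == SIRE_ID
    }


# ---------------------------------------------------------------------------
# Marker genotypes


def _gamete(
    hap0: np.ndarray,
    hap1: np.ndarray,
    chrom_slices: list[slice],
    recomb: float,
    rng: np.random.Generator,
    pinned: Optional[tuple[slice, int]] = None,
) -> np.ndarray:
    """Drop one recombinant gamete from a phased founder.

    ``pinned`` optionally forces the haplotype state over a marker slice
    (the causal co-segregation window)."""
    n = hap0.shape[0]
    state = np.empty(n, dtype=np.int8)
    for sl in chrom_slices:
        m = sl.stop - sl.start
        switches = rng.random(m) < recomb
        switches[0] = rng.random() < 0.5  # random starting haplotype
        state[sl] = np.cumsum(switches) % 2
    if pinned is not None:
        sl, hap = pinned
        state[sl] = hap
    return np.where(state == 0, hap0, hap1)


def simulate_marker_genotypes(
    pedigree: Pedigree, params: SimParams
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Founder allele draw + Mendelian gene dropping with recombination.

    Founder haplotype alleles are Bernoulli(marker_maf) draws of the B
    allele. Within ``cosegregation_window`` of the causal position the sire
    is forced heterozygous with the mutant-bearing haplotype carrying B and
    the dams homozygous A, so the transmitted sire haplotype is observable at
    those markers and affected half-sibs share it by construction — the toy
    analogue of a dense array always containing fully informative markers
    near any locus.
    """
    params.validate()
    rng = params.rng(_STREAM_GENOTYPES)
    m_per = params.markers_per_chromosome
    n_chrom = params.n_chromosomes
    total = m_per * n_chrom
    spacing = params.chromosome_length / (m_per + 1)
    rows = []
    for c in range(1, n_chrom + 1):
        for i in range(1, m_per + 1):
            rows.append((f"SNP{c}_{i}", str(c), int(round(i * spacing))))
    mmap = MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos"]))
    chrom_slices = [slice(c * m_per, (c + 1) * m_per) for c in range(n_chrom)]

    causal_chrom = str(params.causal_chromosome)
    causal_idx = mmap.indices(causal_chrom)
    pos = mmap.df["pos"].to_numpy()
    in_window = np.zeros(total, dtype=bool)
    in_window[causal_idx] = (
        np.abs(pos[causal_idx] - params.causal_pos) <= params.cosegregation_window
    )
    window_slice = None
    if in_window.any():
        w = np.flatnonzero(in_window)
        window_slice = slice(int(w[0]), int(w[-1]) + 1)

    offspring = [ind for ind in pedigree if ind.sire_id == SIRE_ID]
    dams = {ind.dam_id for ind in offspring}
    founders = [ind for ind in pedigree if ind.id == SIRE_ID or ind.id in dams]

    haps = {
        f.id: (
            (rng.random(total) < params.marker_maf).astype(np.int8),
            (rng.random(total) < params.marker_maf).astype(np.int8),
        )
        for f in founders
    }
    if window_slice is not None:
        # sire hap0 = mutant-bearing, carries B in the window; dams carry A/A
        haps[SIRE_ID][0][window_slice] = ALLELE_B
        haps[SIRE_ID][1][window_slice] = ALLELE_A
        for f in founders:
            if f.id != SIRE_ID:
                haps[f.id][0][window_slice] = ALLELE_A
                haps[f.id][1][window_slice] = ALLELE_A

    ids = [ind.id for ind in pedigree]
    alleles = np.empty((len(ids), total, 2), dtype=np.int8)
    row = {iid: k for k, iid in enumerate(ids)}
    for f in founders:
        alleles[row[f.id], :, 0] = haps[f.id][0]
        alleles[row[f.id], :, 1] = haps[f.id][1]
    for ind in offspring:
        pin = None
        if window_slice is not None:
            pin = (window_slice, 0 if ind.affected else 1)
        paternal = _gamete(
            *haps[SIRE_ID],
            chrom_slices,
            params.recombination_rate,
            rng,
            pinned=pin,
        )
        maternal = _gamete(
            *haps[ind.dam_id], chrom_slices, params.recombination_rate, rng
        )
        alleles[row[ind.id], :, 0] = paternal
        alleles[row[ind.id], :, 1] = maternal
    return GenotypeMatrix(ids, alleles), mmap


# ---------------------------------------------------------------------------
# Variant cohorts


@dataclass
class CaseVariant:
    """A raw simulated case variant before it enters the filtering stage."""

    chrom: str
    pos: int
    ref: str
    alt: str
    var_id: str
    genotype: str = "0/1"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantSimulation:
    """Bundle of everything the variant stage of the pipeline consumes."""

    case_variants: list[CaseVariant]
    local_index: set[tuple[str, int, str, str]]
    global_index: set[tuple[str, int, str, str]]
    genes: list[GeneModel]
    candidate_gene_names: list[str]
    reference: RegionReference
    truth: GroundTruth


_BASES = "ACGT"


def _random_base(rng: np.random.Generator, exclude: str = "") -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def simulate_variant_cohorts(
    params: SimParams, regions: Sequence[GenomicInterval]
) -> VariantSimulation:
    """Generate the case variant set, control-cohort indexes, gene models and
    reference sequence.

    Exact counts (deterministic round-half-away-from-zero):

    * ``n_cohort_shared_variants`` present in the case and in >=1 control
      cohort;
    * ``n_private_variants`` absent from both cohorts, of which
      ``round(n_private * private_in_region_fraction)`` lie inside
      ``regions`` — this in-region set includes exactly one planted
      splice-donor GT>AT variant inside a candidate gene and
      ``round(in_region * coding_fraction)`` coding variants placed in
      non-candidate genes.
    """
    params.validate()
    regions = list(regions)
    if not regions:
        raise InvalidDesignError("regions must be non-empty")
    rng = params.rng(_STREAM_VARIANTS)
    L = params.chromosome_length
    chroms = [str(c) for c in range(1, params.n_chromosomes + 1)]

    # anchor region: the one containing the causal locus if present
    causal_chrom = str(params.causal_chromosome)
    anchor = next(
        (r for r in regions if r.contains(causal_chrom, params.causal_pos)),
        regions[0],
    )

    n_in_region = round_half_away(
        params.n_private_variants * params.private_in_region_fraction
    )
    if n_in_region < 1:
        raise InvalidDesignError(
            "private_in_region_fraction too small: no room for the planted "
            "splice-donor variant"
        )
    n_coding = min(round_half_away(n_in_region * params.coding_fraction), n_in_region - 1)
    n_noncoding_in_region = n_in_region - n_coding - 1
    n_out_region = params.n_private_variants - n_in_region

    # --- gene models -------------------------------------------------------
    exon_lengths = [120] * 5
    intron_len = 300
    gene_span = sum(exon_lengths) + 4 * intron_len  # 1800 bp
    gene_gap = 700
    causal_anchor = (
        params.causal_pos
        if anchor.contains(causal_chrom, params.causal_pos)
        else (anchor.start + anchor.end) // 2
    )
    # candidate gene 1 placed so the donor of its intron 2 sits at the causal
    # position: start + e1 + i1 + e2 = start + 540
    first_start = causal_anchor - 540
    n_background = max(2, n_coding)
    n_region_genes = params.n_candidate_genes + n_background
    # lay genes out rightwards from the causal gene, wrapping to the left of
    # it when the region's right edge is reached
    starts: list[int] = []
    right = first_start
    left = first_start
    for _ in range(n_region_genes):
        if right + gene_span <= anchor.end:
            starts.append(right)
            right += gene_span + gene_gap
        else:
            left -= gene_span + gene_gap
            if left < anchor.start:
                raise InvalidDesignError(
                    "linked region too small to place candidate and background genes"
                )
            starts.append(left)
    genes: list[GeneModel] = []
    candidate_names: list[str] = []
    for i, start in enumerate(starts):
        if i < params.n_candidate_genes:
            name = f"CAND{i + 1:03d}"
            candidate_names.append(name)
        else:
            name = f"BKG{i - params.n_candidate_genes + 1:03d}"
        genes.append(
            build_gene(name, anchor.chrom, "+", start, exon_lengths, intron_len)
        )
    # remaining candidates live outside any region, on a different chromosome
    off_chrom = chroms[params.causal_chromosome % params.n_chromosomes]
    start = 100_000
    for i in range(params.n_candidate_genes, params.n_candidate_genes_total):
        name = f"CAND{i + 1:03d}"
        candidate_names.append(name)
        genes.append(build_gene(name, off_chrom, "+", start, exon_lengths, intron_len))
        start += gene_span + gene_gap

    # --- reference sequence (chromosomes that carry region genes) ----------
    seq_chroms = sorted({g.chrom for g in genes if g.chrom == anchor.chrom})
    sequences: dict[str, str] = {}
    base_lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    for chrom in seq_chroms:
        seq = bytearray(base_lut[rng.integers(0, 4, size=L)].tobytes())
        for g in genes:
            if g.chrom == chrom:
                patch_splice_sites(seq, g, offset=1)
        sequences[chrom] = seq.decode()
    reference = RegionReference.from_sequences(sequences)

    def ref_base(chrom: str, pos: int) -> str:
        if chrom in sequences:
            return sequences[chrom][pos - 1]
        return _random_base(rng)

    gene_spans = [g.span for g in genes]

    def in_any(intervals: Sequence[GenomicInterval], chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in intervals)

    used: set[tuple[str, int]] = set()

    def draw_site(want_in_regions: bool, avoid_genes: bool) -> tuple[str, int]:
        while True:
            if want_in_regions:
                r = regions[int(rng.integers(len(regions)))]
                chrom = r.chrom
                pos = int(rng.integers(r.start, r.end + 1))
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(1, L + 1))
                if in_any(regions, chrom, pos):
                    continue
            if (chrom, pos) in used:
                continue
            if avoid_genes and in_any(gene_spans, chrom, pos):
                continue
            used.add((chrom, pos))
            return chrom, pos

    case: list[CaseVariant] = []
    local: set[tuple[str, int, str, str]] = set()
    global_: set[tuple[str, int, str, str]] = set()

    def add_case(chrom: str, pos: int, ref: str, alt: str) -> CaseVariant:
        v = CaseVariant(chrom, pos, ref, alt, f"{chrom}_{pos}_{ref}_{alt}")
        case.append(v)
        return v

    # planted splice-donor variant: intron 2 donor +1 of candidate gene 1
    causal_gene = genes[0]
    gs, _ = causal_gene.intron_bounds(2)
    causal_ref = sequences[causal_gene.chrom][gs - 1]  # 'G' by construction
    causal = add_case(causal_gene.chrom, gs, causal_ref, "A")
    used.add((causal.chrom, causal.pos))

    # cohort-shared variants: in the case and in >=1 control cohort
    for i in range(params.n_cohort_shared_variants):
        chrom, pos = draw_site(want_in_regions=False, avoid_genes=True)
        ref = ref_base(chrom, pos)
        alt = _random_base(rng, exclude=ref)
        v = add_case(chrom, pos, ref, alt)
        local.add(v.key)
        if rng.random() < 0.5:
            global_.add(v.key)

    # private coding variants inside background (non-candidate) gene exons
    for i in range(n_coding):
        g = genes[params.n_candidate_genes + (i % n_background)]
        while True:
            ex = g.exons[int(rng.integers(g.n_exons))]
            pos = int(rng.integers(ex[0] + 2, ex[1] - 1))  # keep off exon edges
            if (g.chrom, pos) not in used:
                used.add((g.chrom, pos))
                break
        ref = ref_base(g.chrom, pos)
        add_case(g.chrom, pos, ref, _random_base(rng, exclude=ref))

    # private non-coding variants inside regions (intergenic)
    for _ in range(n_noncoding_in_region):
        chrom, pos = draw_site(want_in_regions=True, avoid_genes=True)
        ref = ref_base(chrom, pos)
        add_case(chrom, pos, ref, _random_base(rng, exclude=ref))

    # private variants outside regions
    for _ in range(n_out_region):
        chrom, pos = draw_site(want_in_regions=False, avoid_genes=True)
        ref = ref_base(chrom, pos)
        add_case(chrom, pos, ref, _random_base(rng, exclude=ref))

    # control-only background sites (never in the case)
    for _ in range(200):
        chrom, pos = draw_site(want_in_regions=False, avoid_genes=True)
        ref = ref_base(chrom, pos)
        alt = _random_base(rng, exclude=ref)
        (local if rng.random() < 0.5 else global_).add((chrom, pos, ref, alt))

    case.sort(key=lambda v: (int(v.chrom), v.pos))
    truth = GroundTruth(
        causal_variant_id=causal.var_id,
        true_linked_regions=list(regions),
        true_allele_fractions={
            "blood": params.mosaic_fraction_soma,
            "semen": params.mosaic_fraction_germline,
        },
    )
    return VariantSimulation(
        case_variants=case,
        local_index=local,
        global_index=global_,
        genes=genes,
        candidate_gene_names=candidate_names,
        reference=reference,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Allelic depths and gestation


def simulate_allelic_depths(
    true_fraction: float,
    depth: int,
    n_sites: int,
    seed: int,
    tissue: str = "other",
    sample: str = SIRE_ID,
) -> pd.DataFrame:
    """Mutant-allele read/peak counts: Binomial(depth, true_fraction) per
    site, independent across sites.

    Returns a tidy table (sample, tissue, site, mutant_count, total_count).
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise DomainError(f"true_fraction={true_fraction} outside [0, 1]")
    if depth < 1:
        raise DomainError(f"depth={depth} must be >= 1")
    rng = np.random.default_rng([seed, _STREAM_DEPTHS])
    mutant = rng.binomial(depth, true_fraction, size=n_sites)
    return pd.DataFrame(
        {
            "sample": sample,
            "tissue": tissue,
            "site": [f"site{i + 1}" for i in range(n_sites)],
            "mutant_count": mutant.astype(int),
            "total_count": depth,
        }
    )


def simulate_gestation_records(
    params: SimParams, pedigree: Pedigree
) -> pd.DataFrame:
    """Gestation lengths: Normal(mean, sd) per phenotype group, truncated to
    ``gestation_bounds`` (defaults bracket the observed affected deliveries
    at gestation days 269-273)."""
    params.validate()
    offspring = [ind for ind in pedigree if ind.sire_id == SIRE_ID]
    n_affected = sum(ind.affected for ind in offspring)
    if n_affected == 0 or n_affected == len(offspring):
        raise InvalidDesignError(
            "gestation simulation needs at least one normal and one affected calving"
        )
    rng = params.rng(_STREAM_GESTATION)
    lo, hi = params.gestation_bounds
    rows = []
    for ind in offspring:
        mean = (
            params.gestation_mean_affected
            if ind.affected
            else params.gestation_mean_normal
        )
        if params.gestation_sd == 0:
            days = float(np.clip(mean, lo, hi))
        else:
            a = (lo - mean) / params.gestation_sd
            b = (hi - mean) / params.gestation_sd
            days = float(
                scipy.stats.truncnorm.rvs(
                    a, b, loc=mean, scale=params.gestation_sd, random_state=rng
                )
            )
        rows.append(
            {
                "dam": ind.dam_id,
                "status": "affected" if ind.affected else "normal",
                "gestation_days": days,
            }
        )
    return pd.DataFrame(rows)


def params_from_mapping(mapping: dict) -> SimParams:
    """Build SimParams from a plain mapping, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(mapping) - known
    if unknown:
        raise DomainError(f"unknown simulation parameters: {sorted(unknown)}")
    if "gestation_bounds" in mapping:
        mapping = dict(mapping)
        mapping["gestation_bounds"] = tuple(mapping["gestation_bounds"])
    return SimParams(**mapping)
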
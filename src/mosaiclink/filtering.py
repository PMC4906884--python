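"""The private-variant filter cascade.

The funnel that reduces a whole-genome case variant set to one candidate:

1. **private**: keep variants absent from both control cohorts (exact
   site+allele match — a different ALT at a known site is still private);
2. **in linked regions**: keep variants inside the linkage intervals
   (1-based inclusive boundaries);
3. **functional class**: coding (in a CDS exon), splice_site (first/last
   two intronic bases — the canonical GT/AG), or other;
4. **candidate genes**: keep coding/splice variants inside candidate genes
   that overlap the linked regions.

A final segregation check asks whether the surviving variant behaves as a
de novo dominant from a mosaic sire: every affected heterozygous, every dam
homozygous reference, the sire either heterozygous or carrying the allele
at a sub-heterozygous (mosaic) fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .exceptions import InvalidDesignError
from .genome import GenomicInterval, merge_intervals
from .pedigree import Pedigree
from .simulate import CaseVariant, round_half_away
from .splice import GeneModel

logger = logging.getLogger(__name__)

CODING = "coding"
SPLICE_SITE = "splice_site"
OTHER = "other"

VariantKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One case variant travelling through the cascade."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = "0/1"
    var_id: Optional[str] = None
    functional_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InvalidDesignError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.var_id is None:
            self.var_id = f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @classmethod
    def from_case_variant(cls, v: CaseVariant) -> "VariantRecord":
        return cls(
            chrom=v.chrom,
            pos=v.pos,
            ref=v.ref,
            alt=v.alt,
            genotype=v.genotype,
            var_id=v.var_id,
        )


@dataclass(frozen=True)
class CohortIndex:
    """Presence/absence index of a control cohort: exact match on
    (chrom, pos, ref, alt)."""

    sites: frozenset[VariantKey]
    label: str = "cohort"
    size: int = 0

    @classmethod
    def from_keys(
        cls, keys: Iterable[VariantKey], label: str = "cohort", size: int = 0
    ) -> "CohortIndex":
        return cls(sites=frozenset(keys), label=label, size=size)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.sites


def filter_private(
    case_variants: Sequence[VariantRecord],
    local: CohortIndex,
    global_: CohortIndex,
) -> list[VariantRecord]:
    """Variants present only in the case: absent from both cohort indexes.

    Input order is preserved. Records with malformed coordinates are skipped
    with a logged warning.
    """
    out = []
    n_bad = 0
    for rec in case_variants:
        if rec.pos < 1 or not rec.ref or not rec.alt:
            n_bad += 1
            continue
        if rec.key in local or rec.key in global_:
            continue
        out.append(rec)
    if n_bad:
        logger.warning("skipped %d malformed variant record(s)", n_bad)
    return out


def filter_by_regions(
    records: Sequence[VariantRecord],
    regions: Sequence[GenomicInterval],
) -> tuple[list[VariantRecord], float]:
    """Keep variants inside the (merged) regions; boundaries inclusive.

    Returns survivors and the excluded fraction at full precision; use
    :func:`excluded_percent` for the display value.
    """
    merged = merge_intervals(regions)
    if not merged:
        logger.warning("empty region list: all %d variants excluded", len(records))
        return [], 1.0 if records else 0.0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = [
        rec
        for rec in records
        if any(
            iv.start <= rec.pos <= iv.end for iv in by_chrom.get(rec.chrom, ())
        )
    ]
    excluded = 1.0 - len(out) / len(records) if records else 0.0
    return out, excluded


def excluded_percent(n_before: int, n_after: int) -> int:
    """Display value for the region-filter exclusion, rounded
    half-away-from-zero to the nearest integer percent (e.g. 6054 -> 785
    gives 87)."""
    if n_before <= 0:
        return 0
    return round_half_away(100.0 * (1.0 - n_after / n_before))


def classify_functional(
    records: Sequence[VariantRecord],
    genes: Sequence[GeneModel],
    splice_window: int = 2,
) -> dict[str, int]:
    """Assign coding / splice_site / other in place; return class counts.

    coding: position inside a CDS exon; splice_site: within the first or
    last ``splice_window`` bases of an intron (canonical GT/AG for the
    default of 2); other: everything else, including chromosomes without
    gene models.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    counts = {CODING: 0, SPLICE_SITE: 0, OTHER: 0}
    for rec in records:
        cls = OTHER
        for g in by_chrom.get(rec.chrom, ()):
            if not g.span.contains(rec.chrom, rec.pos):
                continue
            if any(s <= rec.pos <= e for s, e in g.exons):
                cls = CODING
                break
            for gs, ge in g.introns_genomic():
                if gs <= rec.pos <= ge and (
                    rec.pos - gs < splice_window or ge - rec.pos < splice_window
                ):
                    cls = SPLICE_SITE
                    break
            if cls != OTHER:
                break
        rec.functional_class = cls
        counts[cls] += 1
    return counts


def candidate_genes_in_regions(
    candidates: Sequence[str],
    gene_coordinates: dict[str, GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> list[str]:
    """Candidate genes whose span overlaps any region by >= 1 bp."""
    merged = merge_intervals(regions)
    out = []
    for name in candidates:
        iv = gene_coordinates.get(name)
        if iv is None:
            logger.warning("candidate gene %s has no coordinates; excluded", name)
            continue
        if any(iv.overlaps(r) for r in merged):
            out.append(name)
    return out


@dataclass
class FilterCascadeResult:
    """Stage counts and survivors of the full funnel."""

    counts: dict[str, int]
    survivors: list[VariantRecord]
    excluded_fraction: float
    candidate_genes_in_regions: list[str] = field(default_factory=list)

    @property
    def excluded_percent_display(self) -> int:
        return excluded_percent(self.counts["private"], self.counts["in_region"])


def run_cascade(
    case_variants: Sequence[VariantRecord],
    local: CohortIndex,
    global_: CohortIndex,
    regions: Sequence[GenomicInterval],
    candidates: Sequence[str],
    genes: Sequence[GeneModel],
) -> FilterCascadeResult:
    """private -> in-region -> functional class -> candidate-gene funnel.

    Stage counts are always emitted, including zeros, so every run shows the
    whole funnel.
    """
    private = filter_private(case_variants, local, global_)
    in_region, excluded = filter_by_regions(private, regions)
    class_counts = classify_functional(in_region, genes)
    gene_coords = {g.gene_id: g.span for g in genes}
    cand_in_regions = candidate_genes_in_regions(candidates, gene_coords, regions)
    cand_set = set(cand_in_regions)
    cand_spans = [
        (name, gene_coords[name]) for name in cand_in_regions
    ]
    survivors = [
        rec
        for rec in in_region
        if rec.functional_class in (CODING, SPLICE_SITE)
        and any(iv.contains(rec.chrom, rec.pos) for _, iv in cand_spans)
    ]
    counts = {
        "input": len(case_variants),
        "private": len(private),
        "in_region": len(in_region),
        "coding": class_counts[CODING],
        "splice_site_in_region": class_counts[SPLICE_SITE],
        "splice_in_candidate": len(survivors),
    }
    logger.info(
        "filter funnel: input=%(input)d private=%(private)d "
        "in_region=%(in_region)d coding=%(coding)d "
        "splice_site=%(splice_site_in_region)d survivors=%(splice_in_candidate)d",
        counts,
    )
    return FilterCascadeResult(
        counts=counts,
        survivors=survivors,
        excluded_fraction=excluded,
        candidate_genes_in_regions=cand_in_regions,
    )


# ---------------------------------------------------------------------------
# Segregation


@dataclass
class SegregationReport:
    """Per-individual genotype concordance with the de novo dominant,
    mosaic-sire model."""

    status: dict[str, str]
    passed: bool
    untyped: list[str]


def segregation_check(
    genotypes: dict[str, Union[str, float]],
    pedigree: Pedigree,
    sire_id: str = "SIRE",
    het_band: tuple[float, float] = (0.35, 0.65),
) -> SegregationReport:
    """PASS iff every affected is heterozygous, every typed dam is
    homozygous reference, and the sire is heterozygous or mosaic (allele
    fraction strictly between 0 and the lower heterozygous bound).

    ``genotypes`` maps individual id to a diploid call ("0/0", "0/1",
    "1/1") or, for the sire, optionally a mutant-allele fraction in [0, 1].
    Individuals without an entry are reported untyped and excluded from the
    verdict.
    """
    status: dict[str, str] = {}
    untyped: list[str] = []
    ok = True
    affected = [i for i in pedigree.affected() if i.sire_id == sire_id]
    dams = {i.dam_id for i in affected if i.dam_id is not None}
    for ind in affected:
        g = genotypes.get(ind.id)
        if g is None:
            status[ind.id] = "untyped"
            untyped.append(ind.id)
            continue
        if g in ("0/1", "1/0"):
            status[ind.id] = "het_ok"
        else:
            status[ind.id] = f"unexpected:{g}"
            ok = False
    for dam in sorted(dams):
        g = genotypes.get(dam)
        if g is None:
            status[dam] = "untyped"
            untyped.append(dam)
            continue
        if g == "0/0":
            status[dam] = "hom_ref_ok"
        else:
            status[dam] = f"carrier:{g}"
            ok = False
    g = genotypes.get(sire_id)
    if g is None:
        status[sire_id] = "untyped"
        untyped.append(sire_id)
    elif isinstance(g, (int, float)):
        frac = float(g)
        if 0.0 < frac < het_band[0]:
            status[sire_id] = f"mosaic:{frac:g}"
        elif het_band[0] <= frac <= het_band[1]:
            status[sire_id] = f"heterozygous_fraction:{frac:g}"
        else:
            status[sire_id] = f"unexpected_fraction:{frac:g}"
            ok = False
    elif g in ("0/1", "1/0"):
        status[sire_id] = "het_ok"
    else:
        status[sire_id] = f"unexpected:{g}"
        ok = False
    return SegregationReport(status=status, passed=ok, untyped=untyped)
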
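"""Gene models, coding-coordinate (HGVS c.) notation and canonical
splice-site disruption.

The model is deliberately minimal: a single transcript per gene whose exons
are all coding (CDS == exons). That is the situation of the variant class the
pipeline hunts for — an intronic single-nucleotide change immediately
adjacent to a CDS exon that destroys the invariant donor ``GT`` (or acceptor
``AG``) dinucleotide. A donor loss at intron *k* is predicted to cause either
skipping of exon *k* or retention of intron *k*; both create frameshifted,
prematurely terminating transcripts whose most likely fate is
nonsense-mediated decay.

Coordinates are 1-based inclusive. Intron offsets follow HGVS: ``+1`` is the
first intronic base 3' of the donor, ``-1`` the last intronic base 5' of the
acceptor, always in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .exceptions import DomainError, ReferenceMismatchError
from .genome import GenomicInterval, RegionReference, revcomp

DONOR = "GT"
ACCEPTOR = "AG"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript, fully coding gene model.

    ``exons`` are genomic (start, end) pairs, 1-based inclusive, in ascending
    genomic order regardless of strand; transcript order is derived.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DomainError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise DomainError("gene model needs at least one exon")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise DomainError(f"exon start {s} > end {e}")
            if s <= prev_end:
                raise DomainError("exons overlap or are unsorted")
            prev_end = e

    # -- geometry ------------------------------------------------------------
    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0][0], self.exons[-1][1])

    @property
    def transcript_exons(self) -> tuple[tuple[int, int], ...]:
        """Exons in 5'->3' transcript order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        """Coding lengths in transcript order."""
        return tuple(e - s + 1 for s, e in self.transcript_exons)

    @property
    def cumulative_coding(self) -> tuple[int, ...]:
        """Cumulative coding length through transcript exon k (1-based k)."""
        out = []
        total = 0
        for length in self.exon_lengths:
            total += length
            out.append(total)
        return tuple(out)

    @property
    def coding_length(self) -> int:
        return self.cumulative_coding[-1]

    def introns_genomic(self) -> list[tuple[int, int]]:
        """Intron (start, end) in ascending genomic order."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(self.n_exons - 1)
        ]

    def intron_bounds(self, k: int) -> tuple[int, int]:
        """Genomic (start, end) of transcript intron k (1-based, intron k
        follows transcript exon k)."""
        gaps = self.introns_genomic()
        j = k - 1 if self.strand == "+" else self.n_exons - 1 - k
        return gaps[j]


@dataclass(frozen=True)
class Location:
    """Where a genomic position falls within a gene model."""

    kind: str  # "exon" | "intron" | "outside"
    index: Optional[int] = None  # 1-based, transcript order
    coding_pos: Optional[int] = None  # set for exonic positions
    intron_offset: Optional[int] = None  # signed, set for intronic positions


def locate(gene: GeneModel, pos: int) -> Location:
    """Map a genomic position to (exon k, coding position) or
    (intron k, signed offset), strand-aware.

    Intronic positions take the offset from the nearer boundary; exact middle
    ties go to the donor side.
    """
    if not gene.span.contains(gene.chrom, pos):
        return Location(kind="outside")
    for j, (s, e) in enumerate(gene.exons):
        if s <= pos <= e:
            if gene.strand == "+":
                t = j
                within = pos - s + 1
            else:
                t = gene.n_exons - 1 - j
                within = e - pos + 1
            before = gene.cumulative_coding[t - 1] if t > 0 else 0
            return Location(kind="exon", index=t + 1, coding_pos=before + within)
    for j, (gs, ge) in enumerate(gene.introns_genomic()):
        if gs <= pos <= ge:
            if gene.strand == "+":
                k = j + 1
                from_donor = pos - gs + 1
                from_acceptor = ge - pos + 1
            else:
                k = gene.n_exons - 1 - j
                from_donor = ge - pos + 1
                from_acceptor = pos - gs + 1
            if from_donor <= from_acceptor:
                return Location(kind="intron", index=k, intron_offset=from_donor)
            return Location(kind="intron", index=k, intron_offset=-from_acceptor)
    # unreachable: span is covered by exons + introns
    return Location(kind="outside")


def c_to_genomic(gene: GeneModel, coding_pos: int, intron_offset: int = 0) -> int:
    """Inverse of :func:`locate` for coding coordinates (with optional
    intronic offset): returns the genomic position."""
    if not 1 <= coding_pos <= gene.coding_length:
        raise DomainError(f"coding position {coding_pos} outside CDS")
    cum = gene.cumulative_coding
    t = next(i for i, c in enumerate(cum) if coding_pos <= c)
    before = cum[t - 1] if t > 0 else 0
    within = coding_pos - before
    s, e = gene.transcript_exons[t]
    if gene.strand == "+":
        g = s + within - 1
        return g + intron_offset
    g = e - within + 1
    return g - intron_offset


def _tx_allele(gene: GeneModel, base: str) -> str:
    return base if gene.strand == "+" else _COMP[base.upper()]


def hgvs_c(gene: GeneModel, pos: int, ref: str, alt: str) -> Optional[str]:
    """HGVS-style c.-notation for a SNV, alleles in transcript orientation.

    Returns ``None`` for positions outside the gene span.
    """
    loc = locate(gene, pos)
    r, a = _tx_allele(gene, ref), _tx_allele(gene, alt)
    if loc.kind == "exon":
        return f"c.{loc.coding_pos}{r}>{a}"
    if loc.kind == "intron":
        k = loc.index
        cum = gene.cumulative_coding
        if loc.intron_offset > 0:
            return f"c.{cum[k - 1]}+{loc.intron_offset}{r}>{a}"
        return f"c.{cum[k - 1] + 1}-{-loc.intron_offset}{r}>{a}"
    return None


@dataclass(frozen=True)
class SpliceAnnotation:
    """Annotation of one variant against one gene model."""

    gene_id: str
    feature_kind: str  # "exon" | "intron" | "outside"
    feature_index: Optional[int]
    hgvs_c: Optional[str]
    donor_site_disrupted: bool = False
    acceptor_site_disrupted: bool = False
    ref_dinucleotide: Optional[str] = None
    alt_dinucleotide: Optional[str] = None
    consequences: frozenset[str] = field(default_factory=frozenset)


def predict_consequence(
    feature_index: Optional[int],
    donor_disrupted: bool,
    acceptor_disrupted: bool,
) -> frozenset[str]:
    """Transcript-level consequences of a canonical splice-site loss.

    Donor loss at intron k: the spliceosome either skips exon k (pairing the
    upstream donor with intron k's acceptor) or fails to remove intron k;
    either aberrant product is expected to be NMD-degraded. Acceptor loss at
    intron k analogously implicates the downstream exon k+1.
    """
    if donor_disrupted and feature_index is not None:
        k = feature_index
        return frozenset(
            {f"exon_skipping:{k}", f"intron_retention:{k}", "nmd_likely"}
        )
    if acceptor_disrupted and feature_index is not None:
        k = feature_index
        return frozenset(
            {f"exon_skipping:{k + 1}", f"intron_retention:{k}", "nmd_likely"}
        )
    return frozenset()


def splice_disruption(
    gene: GeneModel,
    pos: int,
    ref: str,
    alt: str,
    reference: RegionReference,
) -> SpliceAnnotation:
    """Full annotation of a SNV: location, c.-notation, canonical-site check.

    Raises :class:`ReferenceMismatchError` when the reference base at ``pos``
    is not ``ref`` — the variant file and reference are out of sync and any
    dinucleotide logic would be meaningless.
    """
    ref = ref.upper()
    alt = alt.upper()
    genome_base = reference.fetch(gene.chrom, pos, pos).upper()
    if genome_base != ref:
        raise ReferenceMismatchError(
            f"reference has {genome_base} at {gene.chrom}:{pos}, variant REF is {ref}"
        )
    loc = locate(gene, pos)
    notation = hgvs_c(gene, pos, ref, alt)
    if loc.kind != "intron" or abs(loc.intron_offset) > 2:
        return SpliceAnnotation(
            gene_id=gene.gene_id,
            feature_kind=loc.kind,
            feature_index=loc.index,
            hgvs_c=notation,
        )

    gs, ge = gene.intron_bounds(loc.index)
    off = loc.intron_offset
    if off > 0:  # donor side
        if gene.strand == "+":
            dinuc = reference.fetch(gene.chrom, gs, gs + 1).upper()
            idx = off - 1
            sub = alt
        else:
            dinuc = revcomp(reference.fetch(gene.chrom, ge - 1, ge).upper())
            idx = off - 1
            sub = _COMP[alt]
        alt_dinuc = dinuc[:idx] + sub + dinuc[idx + 1 :]
        disrupted = alt_dinuc != DONOR
        return SpliceAnnotation(
            gene_id=gene.gene_id,
            feature_kind="intron",
            feature_index=loc.index,
            hgvs_c=notation,
            donor_site_disrupted=disrupted,
            ref_dinucleotide=dinuc,
            alt_dinucleotide=alt_dinuc,
            consequences=predict_consequence(loc.index, disrupted, False),
        )
    # acceptor side: off in {-1, -2}; transcript-oriented dinucleotide is the
    # last two intronic bases, position -2 first, -1 second.
    if gene.strand == "+":
        dinuc = reference.fetch(gene.chrom, ge - 1, ge).upper()
        idx = 2 + off  # -2 -> 0, -1 -> 1
        sub = alt
    else:
        dinuc = revcomp(reference.fetch(gene.chrom, gs, gs + 1).upper())
        idx = 2 + off
        sub = _COMP[alt]
    alt_dinuc = dinuc[:idx] + sub + dinuc[idx + 1 :]
    disrupted = alt_dinuc != ACCEPTOR
    return SpliceAnnotation(
        gene_id=gene.gene_id,
        feature_kind="intron",
        feature_index=loc.index,
        hgvs_c=notation,
        acceptor_site_disrupted=disrupted,
        ref_dinucleotide=dinuc,
        alt_dinucleotide=alt_dinuc,
        consequences=predict_consequence(loc.index, False, disrupted),
    )


# ---------------------------------------------------------------------------
# Fixture builders


def build_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    exon_lengths: list[int],
    intron_length: int = 300,
) -> GeneModel:
    """Lay out a gene with the given transcript-order exon lengths and a
    uniform intron length, anchored at genomic ``start``."""
    genomic_lengths = exon_lengths if strand == "+" else exon_lengths[::-1]
    exons = []
    pos = start
    for length in genomic_lengths:
        exons.append((pos, pos + length - 1))
        pos += length + intron_length
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=tuple(exons))


def patch_splice_sites(seq: bytearray, gene: GeneModel, offset: int) -> None:
    """Overwrite all intron boundaries of ``gene`` in ``seq`` (a mutable
    byte sequence whose index 0 sits at genomic position ``offset``) with
    the canonical GT...AG, in transcript orientation."""
    for gs, ge in gene.introns_genomic():
        if gene.strand == "+":
            seq[gs - offset] = ord("G")
            seq[gs - offset + 1] = ord("T")
            seq[ge - offset - 1] = ord("A")
            seq[ge - offset] = ord("G")
        else:
            # transcript donor GT maps to genomic ...A,C at the intron end
            seq[ge - offset] = ord("C")  # comp(G)
            seq[ge - offset - 1] = ord("A")  # comp(T)
            seq[gs - offset + 1] = ord("T")  # comp(A)
            seq[gs - offset] = ord("C")  # comp(G)


def col2a1_like_fixture() -> tuple[GeneModel, RegionReference, tuple[str, int, str, str]]:
    """A synthetic COL2A1-like gene model and reference window.

    Synthetic stand-in for the bovine COL2A1 transcript: 54 coding exons laid
    out so the cumulative coding length through exon 36 is 2463, with the
    canonical GT donor at the start of intron 36. The returned variant
    (chrom, pos, G, A) sits at intron 36 position +1, so its annotation is
    c.2463+1G>A with donor GT changed to AT — the variant class the pipeline
    is built to recognise. Real bovine exon coordinates are not bundled; the
    layout (uniform introns, plus strand) is synthetic.
    """
    import numpy as np

    exon_lengths = [68] * 35 + [83] + [54] * 18  # cumulative through exon 36 = 2463
    intron_len = 200
    variant_pos = 32_473_300
    # donor of intron 36 = gene_start + sum(exons 1..36) + 35 introns
    gene_start = variant_pos - (sum(exon_lengths[:36]) + 35 * intron_len)
    gene = build_gene(
        "COL2A1_like", "5", "+", gene_start, exon_lengths, intron_length=intron_len
    )
    span = gene.span
    margin = 50
    offset = span.start - margin
    rng = np.random.default_rng(2463)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    length = span.end + margin - offset + 1
    seq = bytearray(bases[rng.integers(0, 4, size=length)].tobytes())
    patch_splice_sites(seq, gene, offset)
    reference = RegionReference({gene.chrom: (offset, seq.decode())})
    return gene, reference, (gene.chrom, variant_pos, "G", "A")
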
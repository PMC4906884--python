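"""Genomic primitives: intervals, marker maps, genotype matrices, reference
sequence access.

Coordinate convention: 1-based inclusive everywhere inside the package (the
VCF/GFF convention); BED files are converted to/from 0-based half-open only at
the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, InvalidDesignError

# Allele encoding for array genotypes: biallelic SNPs called as A/B.
ALLELE_A = 0
ALLELE_B = 1
MISSING = -1
ALLELE_CHARS = {ALLELE_A: "A", ALLELE_B: "B", MISSING: "0"}
CHAR_ALLELES = {"A": ALLELE_A, "B": ALLELE_B, "0": MISSING}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [start, end] on one chromosome, 1-based inclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise DomainError(f"interval start {self.start} < 1")
        if self.start > self.end:
            raise DomainError(f"interval start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or bookended intervals on the same
    chromosome are merged; output sorted by (chrom, start)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + 1:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


class MarkerMap:
    """Ordered SNP map: columns ``marker``, ``chrom``, ``pos``.

    Markers must be grouped by chromosome with strictly increasing positions
    within each chromosome (the PLINK .map contract).
    """

    def __init__(self, df: pd.DataFrame):
        required = ["marker", "chrom", "pos"]
        if list(df.columns[:3]) != required:
            df = df[required]
        df = df.reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        seen: set[str] = set()
        prev_chrom = None
        prev_pos = None
        for chrom, pos in zip(df["chrom"], df["pos"]):
            if chrom != prev_chrom:
                if chrom in seen:
                    raise InvalidDesignError(
                        f"markers of chromosome {chrom} are not contiguous"
                    )
                seen.add(chrom)
                prev_pos = None
            elif pos <= prev_pos:
                raise InvalidDesignError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )
            prev_chrom, prev_pos = chrom, pos
        self._df = df

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self._df["chrom"] == chrom).to_numpy())

    def positions(self, chrom: str) -> np.ndarray:
        return self._df.loc[self._df["chrom"] == chrom, "pos"].to_numpy()


class GenotypeMatrix:
    """Unphased-looking diploid calls over individuals x markers.

    Internally the two allele slots are ordered (slot 0 = paternal when the
    matrix comes from the simulator) but all public semantics treat the pair
    as unordered, matching what an array genotyping platform reports.
    """

    def __init__(self, ids: Sequence[str], alleles: np.ndarray):
        alleles = np.asarray(alleles, dtype=np.int8)
        if alleles.ndim != 3 or alleles.shape[2] != 2:
            raise InvalidDesignError("alleles must have shape (n_ind, n_markers, 2)")
        if alleles.shape[0] != len(ids):
            raise InvalidDesignError("ids and allele matrix disagree on n_ind")
        self.ids = list(ids)
        self.alleles = alleles
        self._row = {iid: k for k, iid in enumerate(self.ids)}

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def row(self, iid: str) -> int:
        return self._row[iid]

    def genotype(self, iid: str, marker_index: int) -> tuple[int, int]:
        a, b = self.alleles[self._row[iid], marker_index]
        return int(a), int(b)

    def b_allele_counts(self) -> np.ndarray:
        """Count of B alleles per individual x marker; -1 where any allele is
        missing."""
        arr = self.alleles
        counts = (arr == ALLELE_B).sum(axis=2).astype(np.int8)
        counts[(arr == MISSING).any(axis=2)] = MISSING
        return counts


class RegionReference:
    """Reference sequence held in memory, possibly only for windows of each
    chromosome.

    ``windows`` maps chromosome -> (start, seq) where ``start`` is the 1-based
    genomic position of ``seq[0]``. ``fetch`` uses 1-based inclusive
    coordinates, like samtools faidx.
    """

    def __init__(self, windows: Mapping[str, tuple[int, str]]):
        self._windows = dict(windows)

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "RegionReference":
        return cls({chrom: (1, seq) for chrom, seq in seqs.items()})

    @property
    def chromosomes(self) -> list[str]:
        return list(self._windows)

    def window(self, chrom: str) -> tuple[int, str]:
        return self._windows[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._windows:
            raise KeyError(f"no reference sequence for chromosome {chrom!r}")
        off, seq = self._windows[chrom]
        if start < off or end > off + len(seq) - 1:
            raise KeyError(
                f"reference window for {chrom} covers "
                f"[{off}, {off + len(seq) - 1}], requested [{start}, {end}]"
            )
        return seq[start - off : end - off + 1]


class FastaReference:
    """pyfaidx-backed reference with the same ``fetch`` contract."""

    def __init__(self, path: str):
        import pyfaidx

        self._fa = pyfaidx.Fasta(path)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fa[chrom][start - 1 : end]).upper()
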
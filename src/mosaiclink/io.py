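"""Readers and writers for the pipeline's interchange formats.

PED/MAP (PLINK text dialect, alleles A/B), VCF v4.2 (single-sample case
variants, read back through pysam), cohort site lists (tab-separated
CHROM POS REF ALT), GFF3 gene models (read through gffutils), FASTA
reference (read through pyfaidx), BED regions (0-based half-open on disk,
1-based inclusive in memory) and per-marker linkage TSV.

Writers avoid timestamps and environment-dependent fields so a fixed seed
produces byte-identical output files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidDesignError
from .filtering import CohortIndex, VariantKey, VariantRecord
from .genome import (
    ALLELE_CHARS,
    CHAR_ALLELES,
    GenomicInterval,
    GenotypeMatrix,
    MarkerMap,
)
from .linkage import LinkageResult
from .pedigree import Individual, Pedigree
from .splice import GeneModel

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# PED / MAP


def write_ped_map(
    prefix: PathLike,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    mmap: MarkerMap,
    family_id: str = "FAM1",
) -> tuple[Path, Path]:
    """PLINK text .ped/.map; phenotype column 2 = affected, 1 = unaffected."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for _, row in mmap.df.iterrows():
            fh.write(f"{row['chrom']}\t{row['marker']}\t0\t{row['pos']}\n")
    with open(ped_path, "w") as fh:
        for ind in pedigree:
            fields = [
                family_id,
                ind.id,
                ind.sire_id or "0",
                ind.dam_id or "0",
                str(ind.sex),
                "2" if ind.affected else "1",
            ]
            row = genotypes.alleles[genotypes.row(ind.id)]
            for a, b in row:
                fields.append(ALLELE_CHARS[int(a)])
                fields.append(ALLELE_CHARS[int(b)])
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


def read_ped_map(
    ped_path: PathLike, map_path: PathLike
) -> tuple[Pedigree, GenotypeMatrix, MarkerMap]:
    rows = []
    with open(map_path) as fh:
        for line in fh:
            chrom, marker, _, pos = line.split()
            rows.append((marker, chrom, int(pos)))
    mmap = MarkerMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos"]))

    individuals: list[Individual] = []
    ids: list[str] = []
    calls: list[list[int]] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * len(mmap):
                raise InvalidDesignError(
                    f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts)} fields, expected {6 + 2 * len(mmap)}"
                )
            _, iid, sire, dam, sex, pheno = parts[:6]
            individuals.append(
                Individual(
                    id=iid,
                    sire_id=None if sire == "0" else sire,
                    dam_id=None if dam == "0" else dam,
                    sex=int(sex),
                    affected=pheno == "2",
                )
            )
            ids.append(iid)
            calls.append([CHAR_ALLELES[a] for a in parts[6:]])
    alleles = np.array(calls, dtype=np.int8).reshape(len(ids), len(mmap), 2)
    return Pedigree(individuals), GenotypeMatrix(ids, alleles), mmap


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    path: PathLike,
    records: Sequence[VariantRecord],
    contig_lengths: dict[str, int],
    sample: str = "CASE",
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=mosaiclink\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.var_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t.\tGT\t{rec.genotype}\n"
            )
    return path


def read_vcf(path: PathLike) -> list[VariantRecord]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gt = "."
            if samples:
                alleles = rec.samples[samples[0]]["GT"]
                if alleles is not None and None not in alleles:
                    gt = "/".join(str(a) for a in alleles)
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    genotype=gt,
                    var_id=rec.id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Cohort site lists


def write_cohort_index(path: PathLike, index: CohortIndex) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#cohort={index.label}\tsize={index.size}\n")
        fh.write("#CHROM\tPOS\tREF\tALT\n")
        for chrom, pos, ref, alt in sorted(
            index.sites, key=lambda k: (k[0], k[1], k[2], k[3])
        ):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    return path


def read_cohort_index(path: PathLike, label: str = "cohort", size: int = 0) -> CohortIndex:
    keys: set[VariantKey] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("#cohort="):
                    head = dict(
                        part.split("=", 1) for part in line[1:].split("\t") if "=" in part
                    )
                    label = head.get("cohort", label)
                    size = int(head.get("size", size))
                continue
            chrom, pos, ref, alt = line.split()
            keys.add((chrom, int(pos), ref, alt))
    return CohortIndex.from_keys(keys, label=label, size=size)


# ---------------------------------------------------------------------------
# GFF3 / FASTA


def write_gff3(path: PathLike, genes: Sequence[GeneModel]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            fh.write(
                f"{g.chrom}\tmosaiclink\tgene\t{span.start}\t{span.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tmosaiclink\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{j};Parent={g.gene_id}\n"
                )
    return path


def read_gff3(path: PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = tuple(
            sorted(
                (c.start, c.end)
                for c in db.children(feat, featuretype="CDS")
            )
        )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                exons=exons,
            )
        )
    return genes


def write_fasta(path: PathLike, sequences: dict[str, str], width: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# BED regions and linkage tables


def write_regions_bed(path: PathLike, regions: Sequence[GenomicInterval]) -> Path:
    """Internal 1-based inclusive intervals emitted as 0-based half-open BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")
    return path


def read_regions(path: PathLike) -> list[GenomicInterval]:
    """Read BED (3+ columns, 0-based half-open) or a CHROM START END TSV with
    a '#'-prefixed header (taken as 1-based inclusive)."""
    path = Path(path)
    out = []
    one_based = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                one_based = True  # headered TSV convention
                continue
            chrom, start, end = line.split()[:3]
            if one_based:
                out.append(GenomicInterval(chrom, int(start), int(end)))
            else:
                out.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return out


def write_linkage_tsv(path: PathLike, result: LinkageResult) -> Path:
    path = Path(path)
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# Tables


def write_gestation_csv(path: PathLike, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.3f")
    return path


def read_gestation_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_depths_csv(path: PathLike, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_depths_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_outcomes_csv(path: PathLike, statuses: Iterable[str]) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["offspring", "status"])
        for i, status in enumerate(statuses, start=1):
            writer.writerow([f"OFF{i:04d}", status])
    return path


def read_outcomes_csv(path: PathLike) -> list[str]:
    df = pd.read_csv(path)
    return list(df["status"])
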
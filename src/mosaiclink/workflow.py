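"""End-to-end orchestration: simulate -> linkage -> filter -> annotate ->
mosaic -> breeding, one seed, one output directory, one combined report.

Stages write their intermediates in standard formats (PED/MAP, VCF, TSV,
BED, GFF3, FASTA, CSV) so each is independently re-runnable, and the report
carries ground-truth recovery verdicts whenever the inputs came from the
simulator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import breeding as breeding_mod
from . import filtering, io, linkage, mosaicism, simulate, splice
from .exceptions import ConfigError
from .genome import GenomicInterval
from .simulate import SimParams

logger = logging.getLogger(__name__)

_WORKFLOW_FIELDS = {
    "alpha",
    "n_permutations",
    "gap_tolerance",
    "run_linkage",
    "run_filter",
    "run_annotate",
    "run_mosaic",
    "run_breeding",
    "regions_file",
    "out_dir",
    "seed",
    "depth_per_tissue",
    "sites_per_tissue",
}


@dataclass
class RunConfig:
    """Simulation parameters plus stage toggles for one reproducible run."""

    params: SimParams = field(default_factory=SimParams)
    alpha: float = 0.05
    n_permutations: int = 1000
    gap_tolerance: int = 2
    run_linkage: bool = True
    run_filter: bool = True
    run_annotate: bool = True
    run_mosaic: bool = True
    run_breeding: bool = True
    regions_file: Optional[str] = None
    out_dir: str = "mosaiclink_run"
    depth_per_tissue: int = 1000
    sites_per_tissue: int = 3

    @property
    def seed(self) -> int:
        return self.params.seed

    def to_mapping(self) -> dict:
        m = dataclasses.asdict(self.params)
        m["gestation_bounds"] = list(m["gestation_bounds"])
        for name in sorted(_WORKFLOW_FIELDS - {"seed"}):
            if hasattr(self, name):
                m[name] = getattr(self, name)
        return m


def config_from_mapping(mapping: dict) -> tuple[Optional[RunConfig], list[str]]:
    """Typed config from a flat mapping; returns (config or None, all
    violations)."""
    errors: list[str] = []
    param_names = {f.name for f in dataclasses.fields(SimParams)}
    unknown = set(mapping) - param_names - _WORKFLOW_FIELDS
    for key in sorted(unknown):
        errors.append(f"unknown configuration key: {key}")
    pm = {k: v for k, v in mapping.items() if k in param_names}
    if "seed" in mapping:
        pm["seed"] = mapping["seed"]
    if "gestation_bounds" in pm:
        pm["gestation_bounds"] = tuple(pm["gestation_bounds"])
    try:
        params = SimParams(**pm)
    except TypeError as exc:
        errors.append(str(exc))
        params = SimParams()
    errors.extend(params.validation_errors())
    wf = {
        k: v for k, v in mapping.items() if k in _WORKFLOW_FIELDS and k != "seed"
    }
    alpha = wf.get("alpha", 0.05)
    if not 0.0 < alpha < 1.0:
        errors.append(f"alpha={alpha} outside (0, 1)")
    n_perm = wf.get("n_permutations", 1000)
    if n_perm < 1:
        errors.append(f"n_permutations={n_perm} must be positive")
    if errors:
        return None, errors
    return RunConfig(params=params, **wf), errors


def validate_config(path: Union[str, Path]) -> tuple[Optional[RunConfig], list[str]]:
    """Parse a YAML (or key=value) config file; returns the typed config or
    the complete list of violations."""
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config {path}: {exc}") from exc
    if data is None:
        data = {}
    if isinstance(data, str):
        # fall back to key=value lines
        data = {}
        for ln, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{ln}: expected key=value, got {line!r}")
            key, value = line.split("=", 1)
            data[key.strip()] = yaml.safe_load(value.strip())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_mapping(data)


@dataclass
class RunReport:
    """Combined per-stage summaries plus ground-truth recovery verdicts."""

    seed: int
    stages: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "stages": self.stages,
                "ground_truth": self.ground_truth,
                "files": self.files,
            },
            indent=2,
            sort_keys=True,
        )


def run_all(config: RunConfig) -> RunReport:
    """Execute all enabled stages in order, wiring linkage regions into the
    filter and filter survivors into annotation.

    Any stage failure aborts with the stage name; the report written so far
    is persisted in the output directory.
    """
    errors = config.params.validation_errors()
    if errors:
        raise ConfigError("; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    report = RunReport(seed=params.seed)
    stage = "simulate"
    try:
        pedigree = simulate.simulate_pedigree(params)
        genotypes, mmap = simulate.simulate_marker_genotypes(pedigree, params)
        truth_regions = simulate.true_regions(params)
        vsim = simulate.simulate_variant_cohorts(params, truth_regions)
        vsim.truth.transmitted_flags = simulate.transmitted_flags(pedigree)
        truth = vsim.truth

        ped_path, map_path = io.write_ped_map(out / "sim", pedigree, genotypes, mmap)
        case_records = [
            filtering.VariantRecord.from_case_variant(v) for v in vsim.case_variants
        ]
        contigs = {
            str(c): params.chromosome_length
            for c in range(1, params.n_chromosomes + 1)
        }
        vcf_path = io.write_vcf(out / "case.vcf", case_records, contigs)
        local = filtering.CohortIndex.from_keys(vsim.local_index, "local", 118)
        global_ = filtering.CohortIndex.from_keys(vsim.global_index, "global", 1119)
        io.write_cohort_index(out / "cohort_local.tsv", local)
        io.write_cohort_index(out / "cohort_global.tsv", global_)
        io.write_gff3(out / "genes.gff3", vsim.genes)
        seqs = {c: vsim.reference.window(c)[1] for c in vsim.reference.chromosomes}
        io.write_fasta(out / "reference.fa", seqs)
        (out / "candidates.txt").write_text(
            "\n".join(vsim.candidate_gene_names) + "\n"
        )
        io.write_regions_bed(out / "regions_true.bed", truth_regions)
        affected = [i for i in pedigree.affected() if i.sire_id == simulate.SIRE_ID]

        # tissue depths, gestation and outcome tables are generator outputs
        blood = simulate.simulate_allelic_depths(
            params.mosaic_fraction_soma,
            config.depth_per_tissue,
            config.sites_per_tissue,
            seed=params.seed,
            tissue="blood",
        )
        semen = simulate.simulate_allelic_depths(
            params.mosaic_fraction_germline,
            config.depth_per_tissue,
            config.sites_per_tissue,
            seed=params.seed + 1,
            tissue="semen",
        )
        depths = pd.concat([blood, semen], ignore_index=True)
        io.write_depths_csv(out / "allele_depths.csv", depths)
        statuses = [
            breeding_mod.STATUS_CONFIRMED_AFFECTED
            if ind.affected
            else breeding_mod.STATUS_ALIVE_NORMAL
            for ind in pedigree
            if ind.sire_id == simulate.SIRE_ID
        ]
        io.write_outcomes_csv(out / "outcomes.csv", statuses)
        gest = None
        if 0 < len(affected) < params.n_offspring:
            gest = simulate.simulate_gestation_records(params, pedigree)
            io.write_gestation_csv(out / "gestation.csv", gest)
        report.stages["simulate"] = {
            "n_offspring": params.n_offspring,
            "n_affected": len(affected),
            "n_markers": len(mmap),
            "n_case_variants": len(case_records),
        }
        report.files.update(
            {
                "ped": ped_path.name,
                "map": map_path.name,
                "vcf": vcf_path.name,
                "gff3": "genes.gff3",
                "fasta": "reference.fa",
            }
        )

        regions: list[GenomicInterval] = truth_regions
        if config.run_linkage:
            stage = "linkage"
            scan = linkage.genome_scan(
                genotypes,
                pedigree,
                mmap,
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                seed=params.seed,
                gap_tolerance=config.gap_tolerance,
            )
            io.write_linkage_tsv(out / "linkage.tsv", scan)
            io.write_regions_bed(out / "regions_linkage.bed", scan.significant_regions)
            regions = scan.significant_regions
            sig = scan.table["p"] < config.alpha
            report.stages["linkage"] = {
                "n_significant_markers": int(sig.sum()),
                "n_regions": len(scan.significant_regions),
                "max_z": float(scan.table["z"].max()),
                "max_lod": float(scan.table["lod"].max()),
            }
            report.files["linkage"] = "linkage.tsv"
        elif config.regions_file:
            regions = io.read_regions(config.regions_file)

        cascade = None
        if config.run_filter:
            stage = "filter"
            cascade = filtering.run_cascade(
                case_records,
                local,
                global_,
                regions,
                vsim.candidate_gene_names,
                vsim.genes,
            )
            io.write_vcf(
                out / "survivors.vcf", cascade.survivors, contigs
            )
            (out / "cascade.json").write_text(
                json.dumps(
                    {
                        "counts": cascade.counts,
                        "excluded_percent": cascade.excluded_percent_display,
                        "survivors": [r.var_id for r in cascade.survivors],
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            report.stages["filter"] = dict(cascade.counts)
            report.stages["filter"]["excluded_percent"] = (
                cascade.excluded_percent_display
            )

        if config.run_annotate and cascade is not None:
            stage = "annotate"
            gene_by_chrom: dict[str, list[splice.GeneModel]] = {}
            for g in vsim.genes:
                gene_by_chrom.setdefault(g.chrom, []).append(g)
            annotations = []
            for rec in cascade.survivors:
                for g in gene_by_chrom.get(rec.chrom, ()):
                    if not g.span.contains(rec.chrom, rec.pos):
                        continue
                    ann = splice.splice_disruption(
                        g, rec.pos, rec.ref, rec.alt, vsim.reference
                    )
                    annotations.append(
                        {
                            "variant": rec.var_id,
                            "gene": g.gene_id,
                            "feature": f"{ann.feature_kind}{ann.feature_index}",
                            "hgvs_c": ann.hgvs_c,
                            "donor_site_disrupted": ann.donor_site_disrupted,
                            "acceptor_site_disrupted": ann.acceptor_site_disrupted,
                            "ref_dinucleotide": ann.ref_dinucleotide,
                            "alt_dinucleotide": ann.alt_dinucleotide,
                            "consequences": sorted(ann.consequences),
                        }
                    )
            (out / "annotations.json").write_text(
                json.dumps(annotations, indent=2, sort_keys=True)
            )
            report.stages["annotate"] = {"annotations": annotations}

            # segregation of the surviving variant(s)
            calls: dict[str, Union[str, float]] = {}
            for ind in pedigree:
                if ind.sire_id == simulate.SIRE_ID:
                    calls[ind.id] = "0/1" if ind.affected else "0/0"
                elif ind.id != simulate.SIRE_ID:
                    calls[ind.id] = "0/0"
            calls[simulate.SIRE_ID] = params.mosaic_fraction_germline
            seg = filtering.segregation_check(calls, pedigree, simulate.SIRE_ID)
            report.stages["segregation"] = {
                "passed": seg.passed,
                "n_untyped": len(seg.untyped),
            }

        if config.run_mosaic:
            stage = "mosaic"
            est_blood = mosaicism.estimate_fraction(depths, tissue="blood")
            est_semen = mosaicism.estimate_fraction(depths, tissue="semen")
            labels = mosaicism.classify_mosaicism(est_blood, est_semen)
            n_aff = sum(truth.transmitted_flags.values())
            off_est = mosaicism.germline_from_offspring(n_aff, params.n_offspring)
            pval = mosaicism.consistency_test(
                n_aff, params.n_offspring, est_semen.estimate
            )
            report.stages["mosaic"] = {
                "blood": dataclasses.asdict(est_blood),
                "semen": dataclasses.asdict(est_semen),
                "classification": labels,
                "offspring_estimate": dataclasses.asdict(off_est),
                "offspring_vs_semen_p": pval,
            }

        if config.run_breeding:
            stage = "breeding"
            summary = breeding_mod.tally(statuses)
            report.stages["breeding"] = {
                "summary": dataclasses.asdict(summary),
                "affected_percent": summary.affected_percent_display,
            }
            if gest is not None:
                report.stages["breeding"]["gestation"] = (
                    breeding_mod.gestation_analysis(gest)
                )

        stage = "verdict"
        survivor_ids = (
            [r.var_id for r in cascade.survivors] if cascade is not None else []
        )
        report.ground_truth = {
            "causal_variant_id": truth.causal_variant_id,
            "causal_variant_recovered": truth.causal_variant_id in survivor_ids,
            "unique_survivor": len(survivor_ids) == 1,
            "causal_region_significant": any(
                r.contains(str(params.causal_chromosome), params.causal_pos)
                for r in regions
            ),
            "true_allele_fractions": truth.true_allele_fractions,
        }
    except Exception as exc:
        (out / "report.json").write_text(report.to_json())
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(report.to_json())
    return report
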
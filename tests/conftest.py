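import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mosaiclink as ml
from mosaiclink import filtering, simulate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params() -> ml.SimParams:
    return ml.SimParams(seed=1)


@pytest.fixture(scope="session")
def sim_bundle(default_params):
    """One seeded end-to-end simulation shared across tests."""
    ped = ml.simulate_pedigree(default_params)
    geno, mmap = ml.simulate_marker_genotypes(ped, default_params)
    regions = simulate.true_regions(default_params)
    vsim = ml.simulate_variant_cohorts(default_params, regions)
    return {
        "params": default_params,
        "pedigree": ped,
        "genotypes": geno,
        "map": mmap,
        "regions": regions,
        "vsim": vsim,
    }


@pytest.fixture(scope="session")
def case_records(sim_bundle):
    return [
        filtering.VariantRecord.from_case_variant(v)
        for v in sim_bundle["vsim"].case_variants
    ]


@pytest.fixture(scope="session")
def cohort_indexes(sim_bundle):
    vsim = sim_bundle["vsim"]
    return (
        filtering.CohortIndex.from_keys(vsim.local_index, "local", 118),
        filtering.CohortIndex.from_keys(vsim.global_index, "global", 1119),
    )


def random_toy_gene(rng: np.random.Generator) -> ml.GeneModel:
    """A random small gene model on either strand for property tests."""
    n_exons = int(rng.integers(2, 7))
    lengths = rng.integers(3, 120, size=n_exons).tolist()
    introns = rng.integers(7, 300, size=n_exons - 1).tolist()
    start = int(rng.integers(1, 10_000))
    strand = "+" if rng.random() < 0.5 else "-"
    tx_lengths = lengths if strand == "+" else lengths[::-1]
    exons = []
    pos = start
    for i, ln in enumerate(tx_lengths):
        exons.append((pos, pos + ln - 1))
        pos += ln + (introns[i] if i < len(introns) else 0)
    return ml.GeneModel(
        gene_id="toy", chrom="1", strand=strand, exons=tuple(exons)
    )
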
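"""Non-parametric allele-sharing linkage for paternal half-sib families.

At every marker the sire-transmitted allele is deduced for each affected
half-sib by subtracting a compatible maternal allele. The sharing statistic
is the pair count

    S = #{unordered affected pairs that received the same sire allele},

standardised against its exact null moments (each affected inherits either
sire allele independently with probability 1/2, so with k of n sharing one
allele, S = C(k,2) + C(n-k,2) with k ~ Binomial(n, 1/2)) to give the Z-mean
score, and re-expressed as a one-parameter likelihood-ratio LOD:

    l(delta) = sum_f ln(1 + delta * z_f),   LOD = max_{delta in [0, d_max]} l / ln 10.

Chromosome-wide significance is assessed by permutation: transmission
vectors are redrawn i.i.d. Bernoulli(1/2) per informative affected per
marker (preserving each marker's informativeness pattern) and each marker's
empirical p is the fraction of permutations whose chromosome-maximum z
reaches its observed z, with the (r+1)/(N+1) tie-safe estimator.

This is an exact single-point analysis on informative markers; regional
structure comes from merging runs of significant markers. It is a
deliberate simplification of multipoint NPL analysis (no inheritance-vector
HMM), adequate when informative markers flank the causal locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from functools import lru_cache
from math import comb, log, log10
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .exceptions import UndefinedStatisticError
from .genome import ALLELE_B, MISSING, GenomicInterval, GenotypeMatrix, MarkerMap
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

DEFAULT_DELTA_CAP = 1.0


class Transmission(IntEnum):
    """Deduced sire-transmitted allele, or the reason none could be deduced."""

    ALLELE_A = 0
    ALLELE_B = 1
    AMBIGUOUS = -2
    UNINFORMATIVE = -3
    INCONSISTENT = -4
    MISSING = -5


def transmission_matrix(
    genotypes: GenotypeMatrix, pedigree: Pedigree, sire_id: str
) -> tuple[np.ndarray, list[str]]:
    """Vectorised sire-transmission deduction for all offspring x markers.

    Returns an int8 matrix of :class:`Transmission` codes (offspring rows in
    pedigree order) and the offspring ids.
    """
    bc = genotypes.b_allele_counts()
    sire_bc = bc[genotypes.row(sire_id)]
    offspring = [ind for ind in pedigree if ind.sire_id == sire_id]
    ids = [ind.id for ind in offspring]
    out = np.full((len(offspring), genotypes.n_markers), Transmission.MISSING, np.int8)
    sire_het = sire_bc == 1
    sire_hom = (sire_bc == 0) | (sire_bc == 2)
    for i, ind in enumerate(offspring):
        if ind.dam_id is None or ind.dam_id not in genotypes.ids:
            continue
        obc = bc[genotypes.row(ind.id)]
        dbc = bc[genotypes.row(ind.dam_id)]
        valid = (obc != MISSING) & (dbc != MISSING) & (sire_bc != MISSING)
        row = out[i]
        # sire homozygous: transmitted allele known but carries no sharing
        # information
        row[valid & sire_hom] = Transmission.UNINFORMATIVE
        het = valid & sire_het
        row[het & (obc == 0) & (dbc < 2)] = Transmission.ALLELE_A
        row[het & (obc == 0) & (dbc == 2)] = Transmission.INCONSISTENT
        row[het & (obc == 2) & (dbc > 0)] = Transmission.ALLELE_B
        row[het & (obc == 2) & (dbc == 0)] = Transmission.INCONSISTENT
        row[het & (obc == 1) & (dbc == 0)] = Transmission.ALLELE_B
        row[het & (obc == 1) & (dbc == 2)] = Transmission.ALLELE_A
        row[het & (obc == 1) & (dbc == 1)] = Transmission.AMBIGUOUS
    n_incons = int((out == Transmission.INCONSISTENT).sum())
    if n_incons:
        logger.warning(
            "%d offspring-marker genotype(s) Mendelian-inconsistent; excluded",
            n_incons,
        )
    return out, ids


def infer_sire_transmission(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    marker_index: int,
    sire_id: Optional[str] = None,
) -> dict[str, Transmission]:
    """Per-offspring transmitted sire allele at one marker (see
    :func:`transmission_matrix` for the deduction rules)."""
    sire_id = sire_id or pedigree.sires()[0]
    mat, ids = transmission_matrix(genotypes, pedigree, sire_id)
    return {iid: Transmission(int(v)) for iid, v in zip(ids, mat[:, marker_index])}


def spairs(transmissions: Sequence[int]) -> int:
    """Number of unordered pairs sharing the same transmitted sire allele."""
    ts = [int(t) for t in transmissions]
    if any(t not in (Transmission.ALLELE_A, Transmission.ALLELE_B) for t in ts):
        raise UndefinedStatisticError("S-pairs needs unambiguous transmissions")
    if len(ts) < 2:
        raise UndefinedStatisticError("S-pairs needs >= 2 informative transmissions")
    k = sum(1 for t in ts if t == Transmission.ALLELE_B)
    n = len(ts)
    return comb(k, 2) + comb(n - k, 2)


@lru_cache(maxsize=None)
def spairs_null_moments(n_informative: int) -> tuple[float, float]:
    """Exact null mean and variance of S for n informative affected.

    Computed in closed form over k ~ Binomial(n, 1/2) with integer
    arithmetic: E[S] = sum_k C(n,k) S(k) / 2^n (equals C(n,2)/2 by pair
    linearity), and Var from the exact second moment.
    """
    n = int(n_informative)
    if n < 2:
        raise UndefinedStatisticError("null moments need n >= 2")
    total = 2**n
    s1 = 0
    s2 = 0
    for k in range(n + 1):
        w = comb(n, k)
        s = comb(k, 2) + comb(n - k, 2)
        s1 += w * s
        s2 += w * s * s
    mean = s1 / total
    var = s2 / total - mean * mean
    return mean, var


def npl_zscore(s: int, n_informative: int) -> float:
    """Standardised sharing score z = (S - E0[S]) / sqrt(Var0[S])."""
    mean, var = spairs_null_moments(n_informative)
    if var <= 0:
        raise UndefinedStatisticError(f"zero null variance at n={n_informative}")
    return (s - mean) / var**0.5


def kong_cox_lod(
    zscores: Sequence[float], delta_cap: float = DEFAULT_DELTA_CAP
) -> float:
    """Kong-Cox linear-model LOD from per-family z scores at one locus.

    l(delta) = sum_f ln(1 + delta z_f) maximised over delta in [0, d_max],
    where d_max keeps every term positive (min of -1/z over negative z,
    capped at ``delta_cap``). LOD = 0 when the maximiser is delta = 0, i.e.
    when there is no sharing excess (sum z <= 0).
    """
    zs = [float(z) for z in zscores if np.isfinite(z)]
    if not zs:
        raise UndefinedStatisticError("no finite z scores at locus")
    d_max = delta_cap
    for z in zs:
        if z < 0:
            d_max = min(d_max, -1.0 / z * (1.0 - 1e-12))
    if d_max <= 0 or sum(zs) <= 0:
        return 0.0
    if len(zs) == 1:
        # single family: l is monotone in delta, maximum at the boundary
        return max(0.0, log(1.0 + d_max * zs[0])) / log(10.0)

    def neg_ll(delta: float) -> float:
        return -sum(log(1.0 + delta * z) for z in zs)

    res = scipy.optimize.minimize_scalar(
        neg_ll, bounds=(0.0, d_max), method="bounded",
        options={"xatol": 1e-10},
    )
    best = max(-res.fun, -neg_ll(d_max), 0.0)
    return best / log(10.0)


def merge_regions(
    flags: Sequence[bool], mmap: MarkerMap, gap_tolerance: int = 0
) -> list[GenomicInterval]:
    """Merge runs of flagged markers into genomic intervals, bridging up to
    ``gap_tolerance`` consecutive unflagged markers inside a run."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(mmap):
        raise UndefinedStatisticError("flags not aligned with marker map")
    out: list[GenomicInterval] = []
    df = mmap.df
    for chrom in mmap.chromosomes:
        idx = mmap.indices(chrom)
        sig = np.flatnonzero(flags[idx])
        if sig.size == 0:
            continue
        start = prev = sig[0]
        for j in sig[1:]:
            if j - prev - 1 <= gap_tolerance:
                prev = j
            else:
                out.append(
                    GenomicInterval(
                        chrom,
                        int(df["pos"].iloc[idx[start]]),
                        int(df["pos"].iloc[idx[prev]]),
                    )
                )
                start = prev = j
        out.append(
            GenomicInterval(
                chrom,
                int(df["pos"].iloc[idx[start]]),
                int(df["pos"].iloc[idx[prev]]),
            )
        )
    return out


@dataclass
class LinkageResult:
    """Per-marker sharing statistics and the merged significant regions."""

    table: pd.DataFrame  # marker, chrom, pos, S, n_informative, z, lod, p
    significant_regions: list[GenomicInterval]
    n_permutations: int
    alpha: float


def _z_lookup(n_max: int) -> np.ndarray:
    """Z[n, k] for k of n informative sharing allele B; NaN where undefined."""
    Z = np.full((n_max + 1, n_max + 1), np.nan)
    for n in range(2, n_max + 1):
        mean, var = spairs_null_moments(n)
        if var <= 0:
            continue
        for k in range(n + 1):
            s = comb(k, 2) + comb(n - k, 2)
            Z[n, k] = (s - mean) / var**0.5
    return Z


def genome_scan(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    mmap: MarkerMap,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    gap_tolerance: int = 2,
    delta_cap: float = DEFAULT_DELTA_CAP,
    sire_id: Optional[str] = None,
) -> LinkageResult:
    """Single-point allele-sharing scan with chromosome-wide permutation p.

    Markers with fewer than two informative affected transmissions are
    skipped (NaN statistics). Significant markers (p < alpha) are merged
    into regions with :func:`merge_regions`.
    """
    if n_permutations < 100:
        logger.warning(
            "n_permutations=%d < 100: empirical p-values will be unstable",
            n_permutations,
        )
    sire_id = sire_id or pedigree.sires()[0]
    cases = pedigree.affected_half_sibs(sire_id)
    if len(cases) < 2:
        raise UndefinedStatisticError(
            "genome scan needs >= 2 affected half-sibs of one sire"
        )
    mat, ids = transmission_matrix(genotypes, pedigree, sire_id)
    case_rows = [i for i, iid in enumerate(ids) if pedigree[iid].affected]
    tmat = mat[case_rows]

    informative = (tmat == Transmission.ALLELE_A) | (tmat == Transmission.ALLELE_B)
    n_inf = informative.sum(axis=0)
    k_b = ((tmat == Transmission.ALLELE_B) & informative).sum(axis=0)
    n_max = len(case_rows)
    Z = _z_lookup(n_max)
    comb2 = np.array([comb(k, 2) for k in range(n_max + 1)])

    M = len(mmap)
    S = np.full(M, np.nan)
    z = np.full(M, np.nan)
    lod = np.full(M, np.nan)
    ok = n_inf >= 2
    S[ok] = comb2[k_b[ok]] + comb2[n_inf[ok] - k_b[ok]]
    z[ok] = Z[n_inf[ok], k_b[ok]]
    for j in np.flatnonzero(ok & np.isfinite(z)):
        lod[j] = kong_cox_lod([z[j]], delta_cap=delta_cap)

    rng = np.random.default_rng([seed, 7])
    p = np.full(M, np.nan)
    for chrom in mmap.chromosomes:
        idx = mmap.indices(chrom)
        cok = idx[ok[idx] & np.isfinite(z[idx])]
        if cok.size == 0:
            continue
        n_arr = n_inf[cok]
        ks = rng.binomial(n_arr[None, :], 0.5, size=(n_permutations, cok.size))
        null_z = Z[n_arr[None, :], ks]
        chrom_max = null_z.max(axis=1)
        exceed = (chrom_max[:, None] >= z[cok][None, :]).sum(axis=0)
        p[cok] = (exceed + 1) / (n_permutations + 1)

    flags = np.nan_to_num(p, nan=1.0) < alpha
    regions = merge_regions(flags, mmap, gap_tolerance=gap_tolerance)
    table = pd.DataFrame(
        {
            "marker": mmap.df["marker"],
            "chrom": mmap.df["chrom"],
            "pos": mmap.df["pos"],
            "S": S,
            "n_informative": n_inf,
            "z": z,
            "lod": lod,
            "p": p,
        }
    )
    return LinkageResult(
        table=table,
        significant_regions=regions,
        n_permutations=n_permutations,
        alpha=alpha,
    )
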
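"""Quantifying somatic and germline mosaicism.

A founder who acquires a dominant mutation early in development carries it
in a fraction of somatic cells (visible as a minor allele peak in blood)
and a fraction of germ cells (visible in semen, and — for a fully penetrant
lethal dominant — directly equal to the expected prevalence of affected
offspring, since each conceptus receives exactly one paternal gamete).

Allele-signal ratios are treated as binomial counts (mutant reads / total
reads per assayed site); the pooled fraction carries a Wilson score
interval, which stays inside [0, 1] and behaves at the boundaries where the
Wald interval degenerates. The offspring ratio itself is a second,
independent estimator of the germline fraction, and an exact two-sided
binomial test (minimum-likelihood method) formalises "the offspring
prevalence is consistent with the semen fraction".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

from .exceptions import DomainError, UndefinedStatisticError

DEFAULT_ZERO_BAND = 0.01
DEFAULT_HET_BAND = (0.35, 0.65)


@dataclass(frozen=True)
class MosaicEstimate:
    """A binomial proportion with its 95% Wilson interval."""

    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_effective: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0:
            raise DomainError(
                f"inconsistent estimate/CI: {self.ci_low}, {self.estimate}, "
                f"{self.ci_high}"
            )


def wilson_estimate(k: int, n: int, conf: float = 0.95) -> MosaicEstimate:
    if n <= 0:
        raise UndefinedStatisticError("zero total depth: fraction undefined")
    if not 0 <= k <= n:
        raise DomainError(f"mutant count {k} outside [0, {n}]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    est = k / n
    # guard against float noise at the boundaries (e.g. lo = 1e-18 when k=0)
    lo = min(max(float(lo), 0.0), est)
    hi = max(min(float(hi), 1.0), est)
    return MosaicEstimate(
        estimate=est,
        ci_low=lo,
        ci_high=hi,
        method="wilson",
        n_effective=n,
    )


def estimate_fraction(
    depths: pd.DataFrame, sample: Optional[str] = None, tissue: Optional[str] = None
) -> MosaicEstimate:
    """Pooled mutant-allele fraction over all sites of one sample/tissue.

    ``depths`` follows the tidy layout of
    :func:`mosaiclink.simulate.simulate_allelic_depths`
    (sample, tissue, site, mutant_count, total_count).
    """
    sub = depths
    if sample is not None:
        sub = sub[sub["sample"] == sample]
    if tissue is not None:
        sub = sub[sub["tissue"] == tissue]
    k = int(sub["mutant_count"].sum())
    n = int(sub["total_count"].sum())
    return wilson_estimate(k, n)


def expected_affected_fraction(germline_fraction: float) -> float:
    """Expected affected-offspring prevalence under the fully penetrant
    lethal dominant model: the identity map — each conceptus receives one
    sire gamete and is affected iff that gamete is mutant."""
    if not 0.0 <= germline_fraction <= 1.0:
        raise DomainError(f"germline_fraction={germline_fraction} outside [0, 1]")
    return germline_fraction


def germline_from_offspring(n_affected: int, n_total: int) -> MosaicEstimate:
    """Germline fraction estimated from offspring outcomes: the ML estimate
    n_affected / n_total with its Wilson interval."""
    return wilson_estimate(n_affected, n_total)


def consistency_test(
    n_affected: int, n_total: int, reference_fraction: float
) -> float:
    """Exact two-sided binomial p for the offspring count against a
    reference fraction (minimum-likelihood two-sided method: sums P(X=k)
    over all k with P(X=k) <= P(X=n_affected))."""
    if not 0.0 <= reference_fraction <= 1.0:
        raise DomainError(f"reference_fraction={reference_fraction} outside [0, 1]")
    if n_total <= 0:
        raise UndefinedStatisticError("n_total must be positive")
    if reference_fraction in (0.0, 1.0):
        concordant = (reference_fraction == 0.0 and n_affected == 0) or (
            reference_fraction == 1.0 and n_affected == n_total
        )
        return 1.0 if concordant else 0.0
    return float(
        scipy.stats.binomtest(
            n_affected, n_total, reference_fraction, alternative="two-sided"
        ).pvalue
    )


def classify_tissue(
    est: MosaicEstimate,
    zero_band: float = DEFAULT_ZERO_BAND,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> str:
    """absent / mosaic / heterozygous / high for one tissue estimate."""
    if est.ci_high < zero_band:
        return "absent"
    if est.ci_high < het_band[0]:
        return "mosaic"
    if est.ci_low <= het_band[1] and est.ci_high >= het_band[0]:
        return "heterozygous"
    return "high"


def classify_mosaicism(
    blood: MosaicEstimate,
    semen: MosaicEstimate,
    zero_band: float = DEFAULT_ZERO_BAND,
    het_band: tuple[float, float] = DEFAULT_HET_BAND,
) -> dict[str, str]:
    """Combined carrier status from blood (soma) and semen (germline)
    estimates.

    somatic_and_germline_mosaic: both tissues mosaic; germline_only: semen
    mosaic with no blood signal; somatic_only: the converse;
    constitutional_heterozygote: both near 0.5; non_carrier: neither tissue
    carries the allele. Anything else is labelled indeterminate.
    """
    b = classify_tissue(blood, zero_band, het_band)
    s = classify_tissue(semen, zero_band, het_band)
    if b == "mosaic" and s == "mosaic":
        combined = "somatic_and_germline_mosaic"
    elif s == "mosaic" and b == "absent":
        combined = "germline_only_mosaic"
    elif b == "mosaic" and s == "absent":
        combined = "somatic_only_mosaic"
    elif b == "heterozygous" and s == "heterozygous":
        combined = "constitutional_heterozygote"
    elif b == "absent" and s == "absent":
        combined = "non_carrier"
    else:
        combined = "indeterminate"
    return {"blood": b, "semen": s, "combined": combined}
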
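"""Breeding-outcome tally and gestation-length comparison.

The questionnaire arithmetic: of all recorded offspring of the sire, those
born alive and ear-tagged are regarded normal; owners of the rest are
followed up and report each calf as affected ("bulldog calf"), of normal
proportions, or unresolvable (excluded). The affected ratio uses a
denominator that drops only the excluded calves:

    affected_ratio = confirmed_affected / (total_recorded - excluded)

so e.g. counts (521, 412, 64, 39, 6) give 64/515 = 12.4%.

Gestation lengths of normal vs affected calvings are compared with the
Welch two-sample t-test (unequal variances, Welch–Satterthwaite degrees of
freedom, two-sided p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .exceptions import InconsistentTallyError, UndefinedStatisticError

STATUS_ALIVE_NORMAL = "alive_normal"
STATUS_CONFIRMED_AFFECTED = "confirmed_affected"
STATUS_REPORTED_NORMAL = "reported_normal"
STATUS_EXCLUDED = "excluded"
STATUSES = (
    STATUS_ALIVE_NORMAL,
    STATUS_CONFIRMED_AFFECTED,
    STATUS_REPORTED_NORMAL,
    STATUS_EXCLUDED,
)


@dataclass(frozen=True)
class BreedingSummary:
    total_recorded: int
    alive_normal: int
    followed_up: int
    confirmed_affected: int
    reported_normal: int
    excluded: int
    affected_ratio: float
    denominator: int

    def __post_init__(self) -> None:
        checks = (
            (
                "followed_up = total_recorded - alive_normal",
                self.followed_up == self.total_recorded - self.alive_normal,
            ),
            (
                "confirmed_affected + reported_normal + excluded = followed_up",
                self.confirmed_affected + self.reported_normal + self.excluded
                == self.followed_up,
            ),
            (
                "denominator = total_recorded - excluded",
                self.denominator == self.total_recorded - self.excluded,
            ),
        )
        for identity, holds in checks:
            if not holds:
                raise InconsistentTallyError(f"identity violated: {identity}")
        if self.denominator > 0:
            expect = self.confirmed_affected / self.denominator
            if abs(self.affected_ratio - expect) > 1e-12:
                raise InconsistentTallyError(
                    "identity violated: affected_ratio = confirmed_affected/denominator"
                )

    @property
    def affected_percent_display(self) -> float:
        """One-decimal percent, e.g. 12.4."""
        return round(100.0 * self.affected_ratio, 1)


def tally(records: Iterable[str]) -> BreedingSummary:
    """Summarise per-offspring outcome statuses.

    ``records`` holds one status per recorded offspring, from
    :data:`STATUSES`. The summary's internal identities are re-checked on
    construction; inconsistent counts raise naming the failing identity.
    """
    counts = {s: 0 for s in STATUSES}
    total = 0
    for status in records:
        if status not in counts:
            raise InconsistentTallyError(
                f"unknown outcome status {status!r}; expected one of {STATUSES}"
            )
        counts[status] += 1
        total += 1
    return summary_from_counts(
        total_recorded=total,
        alive_normal=counts[STATUS_ALIVE_NORMAL],
        confirmed_affected=counts[STATUS_CONFIRMED_AFFECTED],
        reported_normal=counts[STATUS_REPORTED_NORMAL],
        excluded=counts[STATUS_EXCLUDED],
    )


def summary_from_counts(
    total_recorded: int,
    alive_normal: int,
    confirmed_affected: int,
    reported_normal: int,
    excluded: int,
) -> BreedingSummary:
    """Build (and validate) a summary directly from the questionnaire
    counts."""
    followed_up = total_recorded - alive_normal
    denominator = total_recorded - excluded
    ratio = confirmed_affected / denominator if denominator > 0 else 0.0
    return BreedingSummary(
        total_recorded=total_recorded,
        alive_normal=alive_normal,
        followed_up=followed_up,
        confirmed_affected=confirmed_affected,
        reported_normal=reported_normal,
        excluded=excluded,
        affected_ratio=ratio,
        denominator=denominator,
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    pvalue: float


def welch_t(x: Iterable[float], y: Iterable[float]) -> WelchResult:
    """Welch two-sample t-test, two-sided.

    t = (mean x - mean y) / sqrt(s2x/nx + s2y/ny) with Welch–Satterthwaite
    degrees of freedom. Undefined (raises) when either sample has fewer
    than two values or when both samples have zero variance.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise UndefinedStatisticError("Welch t needs >= 2 values per sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise UndefinedStatisticError("both samples have zero variance")
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), pvalue=float(min(p, 1.0)))


def gestation_analysis(table: pd.DataFrame) -> dict:
    """Group means and the Welch test for a gestation table with columns
    ``status`` ("normal"/"affected") and ``gestation_days``."""
    normal = table.loc[table["status"] == "normal", "gestation_days"].to_numpy()
    affected = table.loc[table["status"] == "affected", "gestation_days"].to_numpy()
    if len(normal) < 2 or len(affected) < 2:
        raise UndefinedStatisticError(
            "gestation comparison needs >= 2 records per group"
        )
    res = welch_t(normal, affected)
    return {
        "n_normal": int(len(normal)),
        "n_affected": int(len(affected)),
        "mean_normal": round(float(normal.mean()), 1),
        "mean_affected": round(float(affected.mean()), 1),
        "t": res.t,
        "df": res.df,
        "pvalue": res.pvalue,
    }
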
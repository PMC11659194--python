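"""Distributional-inequity metrics per demographic group.

Two complementary views of how a group is distributed across spot
categories:

* descriptive statistics (mean, median, IQR, Tukey whiskers) of the
  group's DA-level percentage within each category, and
* a simple OLS regression of the group's percentage on the ordinal spot
  code (1 = sour .. 4 = sweet).

A negative, statistically significant slope for a vulnerable group means
the group is concentrated toward the sour end — the operational definition
of distributional inequity used throughout.  The slope is a relative
summary for comparing groups and combinations within one region and year;
it is not a causal or physical model.  Codes 1-4 are always used, even for
combinations with no risky spots, so slopes are comparable across
combinations; a sensitivity variant drops risky DAs first.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import DATable, UndefinedResultError, UsageError
from .spots import SpotAssignment, SpotCategory

logger = logging.getLogger("sweetspots")

__all__ = [
    "GroupSpotStats",
    "RegressionResult",
    "UndefinedSlopeError",
    "describe_by_spot",
    "fit_spot_regression",
    "inequity_matrix",
    "grid_frame",
]

SIGNIFICANCE_LEVEL = 0.05


class UndefinedSlopeError(UndefinedResultError):
    """The regression slope is undefined (no variance in spot codes)."""


@dataclass(frozen=True)
class GroupSpotStats:
    """Summary of a group's DA percentages within one spot category.

    Whiskers are the most extreme values inside the Tukey fences
    q1 - 1.5*IQR and q3 + 1.5*IQR, i.e. the min and max excluding
    outliers, matching box-plot semantics.
    """

    group: str
    category: SpotCategory
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


@dataclass(frozen=True)
class RegressionResult:
    """OLS of a group's DA percentage on the spot code for one combination.

    ``slope`` is in percentage points per one-step improvement in spot
    category.  ``significant`` is p <= 0.05 (two-sided t-test on the
    slope); ``inequity`` is True only for a vulnerable group with a
    significant negative slope.
    """

    group: str
    combination: str
    slope: float
    intercept: float
    p_value: float
    n: int
    vulnerable: bool = True
    exclude_risky: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value <= SIGNIFICANCE_LEVEL

    @property
    def inequity(self) -> bool:
        return self.vulnerable and self.significant and self.slope < 0


def describe_by_spot(
    assignment: SpotAssignment, table: DATable, group: str
) -> dict[SpotCategory, GroupSpotStats]:
    """Per-category descriptive statistics of a group's DA percentages.

    Categories with no DAs (or none with the group observed) are absent
    from the result rather than reported as zeros.
    """
    pct = table.demo(group)
    joined = assignment.frame.join(pct.rename("pct"), how="inner").dropna(
        subset=["pct"]
    )
    out: dict[SpotCategory, GroupSpotStats] = {}
    for cat in SpotCategory:
        vals = joined.loc[joined["code"] == int(cat), "pct"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
        out[cat] = GroupSpotStats(
            group=group,
            category=cat,
            n=int(vals.size),
            mean=float(vals.mean()),
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
        )
    return out


def fit_spot_regression(
    assignment: SpotAssignment,
    table: DATable,
    group: str,
    exclude_risky: bool = False,
    vulnerable: bool = True,
) -> RegressionResult:
    """OLS slope of a group's DA percentage on the spot code (1-4).

    DAs are included only if classified under this combination with the
    group percentage observed.  With ``exclude_risky`` the RISKY DAs are
    dropped first (sensitivity variant); on a combination with no risky
    spots this is identical to the full fit.
    """
    pct = table.demo(group)
    joined = assignment.frame.join(pct.rename("pct"), how="inner").dropna(
        subset=["pct"]
    )
    if exclude_risky:
        joined = joined[joined["code"] != int(SpotCategory.RISKY)]
    x = joined["code"].to_numpy(dtype=float)
    y = joined["pct"].to_numpy(dtype=float)
    if x.size < 3:
        raise UsageError(
            f"fit_spot_regression({group!r}, {assignment.combination!r}): "
            f"needs >= 3 DAs, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise UndefinedSlopeError(
            f"fit_spot_regression({group!r}, {assignment.combination!r}): "
            "all DAs in one spot category; slope undefined"
        )
    if np.ptp(y) == 0:
        # flat response: slope exactly 0 and trivially non-significant
        slope, intercept, p = 0.0, float(y[0]), 1.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, p = float(fit.slope), float(fit.intercept), float(fit.pvalue)
    if abs(p - SIGNIFICANCE_LEVEL) < 1e-12:
        logger.warning(
            "p-value exactly at the %.2f threshold for %s x %s; counted significant",
            SIGNIFICANCE_LEVEL,
            group,
            assignment.combination,
        )
    return RegressionResult(
        group=group,
        combination=assignment.combination,
        slope=slope,
        intercept=intercept,
        p_value=p,
        n=int(x.size),
        vulnerable=vulnerable,
        exclude_risky=exclude_risky,
    )


def inequity_matrix(
    assignments: Iterable[SpotAssignment],
    table: DATable,
    groups: Sequence[str],
    vulnerable: Iterable[str] | None = None,
    exclude_risky: bool = False,
    p_adjust: str = "none",
) -> dict[tuple[str, str], RegressionResult]:
    """One regression per group x combination (the inequity heat-map grid).

    ``vulnerable`` names the groups whose negative slopes count as
    inequity (a normative list, so it is configuration, not code); by
    default every group is treated as vulnerable.  ``p_adjust`` may be
    ``"bh"`` for a Benjamini-Hochberg correction across the grid; the
    default matches the uncorrected per-cell test.
    """
    if p_adjust not in {"none", "bh"}:
        raise UsageError(f"unknown p_adjust {p_adjust!r}; use 'none' or 'bh'")
    vuln = set(groups) if vulnerable is None else set(vulnerable)
    results: dict[tuple[str, str], RegressionResult] = {}
    for assignment in assignments:
        for group in groups:
            results[(group, assignment.combination)] = fit_spot_regression(
                assignment,
                table,
                group,
                exclude_risky=exclude_risky,
                vulnerable=group in vuln,
            )
    if p_adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        keys = list(results)
        raw = [results[k].p_value for k in keys]
        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        for k, p in zip(keys, adj):
            results[k] = replace(results[k], p_value=float(p))
    return results


def grid_frame(
    results: dict[tuple[str, str], RegressionResult], p_adjust: str = "none"
) -> pd.DataFrame:
    """Tidy frame of an inequity grid (one row per group x combination)."""
    rows = [
        {
            "group": r.group,
            "combination": r.combination,
            "slope": r.slope,
            "intercept": r.intercept,
            "p_value": r.p_value,
            "n": r.n,
            "significant": r.significant,
            "inequity": r.inequity,
            "p_adjust": p_adjust,
        }
        for r in results.values()
    ]
    columns = [
        "group",
        "combination",
        "slope",
        "intercept",
        "p_value",
        "n",
        "significant",
        "inequity",
        "p_adjust",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns].sort_values(
        ["group", "combination"]
    ).reset_index(drop=True)
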
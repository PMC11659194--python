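"""Classification of inequity change between two census years.

For each group x combination cell, the two years' regression results are
compared on the inequity flag and the slope:

* IMPROVED - inequity in year A but not in year B, or inequity in both
  with the slope moving toward positive (less negative);
* WORSENED - the mirror image: inequity appearing, or the slope moving
  further negative while inequity persists;
* NONE     - inequity in neither year, or an exact slope tie with
  inequity in both (flagged in the log).

"Increased" is numerical: a slope going from -5 to -3 has increased,
meaning a shallower gradient of the vulnerable group toward sour spots.
The verdict is a pure function of the two results, so swapping the years
maps IMPROVED <-> WORSENED and fixes NONE.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .core import UsageError
from .equity import RegressionResult

logger = logging.getLogger("sweetspots")

__all__ = ["Verdict", "ChangeClassification", "classify_change", "change_matrix", "change_frame"]


class Verdict(str, Enum):
    IMPROVED = "improved"
    WORSENED = "worsened"
    NONE = "none"


@dataclass(frozen=True)
class ChangeClassification:
    """Verdict for one group x combination cell between two years."""

    group: str
    combination: str
    year_a_result: RegressionResult
    year_b_result: RegressionResult
    verdict: Verdict


def classify_change(
    a: RegressionResult, b: RegressionResult
) -> ChangeClassification:
    """Compare two years' regressions for the same group and combination.

    A cell that flips from significant-negative to significant-positive
    counts as IMPROVED (inequity disappeared); the flip itself is logged
    since it is a larger change than the taxonomy distinguishes.
    """
    if a.group != b.group or a.combination != b.combination:
        raise UsageError(
            "classify_change: results refer to different cells "
            f"({a.group!r}/{a.combination!r} vs {b.group!r}/{b.combination!r})"
        )
    if a.inequity and not b.inequity:
        verdict = Verdict.IMPROVED
        if b.significant and b.slope > 0:
            logger.info(
                "cell %s x %s flipped from significant-negative to "
                "significant-positive; classified improved",
                a.group,
                a.combination,
            )
    elif not a.inequity and b.inequity:
        verdict = Verdict.WORSENED
    elif a.inequity and b.inequity:
        if b.slope > a.slope:
            verdict = Verdict.IMPROVED
        elif b.slope < a.slope:
            verdict = Verdict.WORSENED
        else:
            logger.warning(
                "exact slope tie with inequity in both years for %s x %s; "
                "no change identified",
                a.group,
                a.combination,
            )
            verdict = Verdict.NONE
    else:
        verdict = Verdict.NONE
    return ChangeClassification(
        group=a.group,
        combination=a.combination,
        year_a_result=a,
        year_b_result=b,
        verdict=verdict,
    )


def change_matrix(
    grid_a: Mapping[tuple[str, str], RegressionResult],
    grid_b: Mapping[tuple[str, str], RegressionResult],
) -> dict[tuple[str, str], ChangeClassification]:
    """Cell-wise change verdicts for two inequity grids over the same cells."""
    if set(grid_a) != set(grid_b):
        only_a = set(grid_a) - set(grid_b)
        only_b = set(grid_b) - set(grid_a)
        raise UsageError(
            f"change_matrix: grids cover different cells "
            f"(only in a: {sorted(only_a)[:3]}, only in b: {sorted(only_b)[:3]})"
        )
    return {key: classify_change(grid_a[key], grid_b[key]) for key in grid_a}


def change_frame(
    changes: Mapping[tuple[str, str], ChangeClassification]
) -> pd.DataFrame:
    """Tidy frame of a change grid (group, combination, slopes, verdict)."""
    rows = [
        {
            "group": c.group,
            "combination": c.combination,
            "slope_a": c.year_a_result.slope,
            "slope_b": c.year_b_result.slope,
            "inequity_a": c.year_a_result.inequity,
            "inequity_b": c.year_b_result.inequity,
            "verdict": c.verdict.value,
        }
        for c in changes.values()
    ]
    columns = [
        "group",
        "combination",
        "slope_a",
        "slope_b",
        "inequity_a",
        "inequity_b",
        "verdict",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns].sort_values(
        ["group", "combination"]
    ).reset_index(drop=True)
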
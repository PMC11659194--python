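"""Two-variable sweet/sour/risky/medium spot classification.

Each environmental variable is discretized into performance classes 1-4
(1 = most unfavorable to health, 4 = most favorable) by one of two break
methods; a DA's pair of classes for two variables is then mapped to a spot
category by a combination-specific rule set that encodes the health
synergy or trade-off between the variables:

* SWEET  - both variables favorable (benefits may reinforce each other);
* SOUR   - both unfavorable (burdens may compound);
* RISKY  - a benefit undermined and possibly amplified into harm by a
  co-located burden (the canonical case: highly walkable but heavily
  NO2-polluted streets, where active travel raises pollutant intake);
* MEDIUM - everything else.

Spot categories carry fixed ordinal codes (SOUR=1, RISKY=2, MEDIUM=3,
SWEET=4) used as the regressor in the inequity analysis.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DATable,
    DegenerateVariableError,
    Direction,
    FormatError,
    UndefinedResultError,
    UsageError,
    ValidationError,
)

logger = logging.getLogger("sweetspots")

__all__ = [
    "BreakMethod",
    "SpotCategory",
    "ClassBreaks",
    "RuleSet",
    "SpotAssignment",
    "compute_breaks",
    "assign_class",
    "assign_classes",
    "classify_pair",
    "builtin_rulesets",
    "rulesets_from_config",
    "classify_table",
    "count_spots",
    "spot_proportions",
]


class BreakMethod(str, Enum):
    """How cutpoints between the four performance classes are chosen.

    QUARTILE puts the cutpoints at the 25th/50th/75th percentiles of the DA
    values, so each class holds (nearly) the same number of DAs even for
    highly skewed variables.  EVEN_BREAKS splits the observed [min, max]
    range into four equal-width intervals, ranking DAs by absolute value.
    """

    QUARTILE = "quartile"
    EVEN_BREAKS = "even_breaks"


class SpotCategory(IntEnum):
    """Spot category with its fixed ordinal code (1 worst .. 4 best)."""

    SOUR = 1
    RISKY = 2
    MEDIUM = 3
    SWEET = 4

    @property
    def code(self) -> int:
        return int(self)


@dataclass(frozen=True)
class ClassBreaks:
    """Three ascending cutpoints splitting one variable into classes 1-4."""

    variable: str
    method: BreakMethod
    cutpoints: tuple[float, float, float]
    direction: Direction

    def __post_init__(self) -> None:
        c = self.cutpoints
        if len(c) != 3:
            raise ValidationError("ClassBreaks needs exactly 3 cutpoints")
        if not (c[0] <= c[1] <= c[2]):
            raise ValidationError(f"cutpoints not ascending: {c}")
        if len(set(c)) < 3:
            warnings.warn(
                f"tied cutpoints for {self.variable!r}: {c}; "
                "tied classes will be merged toward the lower bin",
                stacklevel=3,
            )


def compute_breaks(
    table: DATable, variable: str, method: BreakMethod
) -> ClassBreaks:
    """Compute class cutpoints for one variable over a table's DAs.

    Raises :class:`DegenerateVariableError` when every value is identical;
    warns (and proceeds) when fewer than 4 distinct values exist.
    """
    method = BreakMethod(method)
    values = table.env(variable).dropna().to_numpy(dtype=float)
    if values.size == 0:
        raise DegenerateVariableError(f"{variable!r}: no non-missing values")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateVariableError(
            f"{variable!r}: all values identical ({vmin}); cannot form classes"
        )
    if np.unique(values).size < 4:
        warnings.warn(
            f"{variable!r}: fewer than 4 distinct values; classes will be coarse",
            stacklevel=2,
        )
    if method is BreakMethod.EVEN_BREAKS:
        step = (vmax - vmin) / 4.0
        cut = (vmin + step, vmin + 2 * step, vmin + 3 * step)
    else:
        q = np.percentile(values, [25.0, 50.0, 75.0])  # linear interpolation
        cut = (float(q[0]), float(q[1]), float(q[2]))
    return ClassBreaks(
        variable=variable,
        method=method,
        cutpoints=cut,
        direction=table.registry[variable].direction,
    )


def assign_classes(
    values: np.ndarray | pd.Series, breaks: ClassBreaks
) -> np.ndarray:
    """Vectorized class assignment; missing values yield 0 (no class).

    Bins are left-open/right-closed (a value exactly on a cutpoint falls in
    the lower bin; the lowest bin is closed below).  For LOW_IS_GOOD
    variables the bin order is reversed so the highest values get class 1.
    """
    arr = np.asarray(values, dtype=float)
    out = np.zeros(arr.shape, dtype=int)
    ok = np.isfinite(arr)
    bins = np.searchsorted(np.asarray(breaks.cutpoints), arr[ok], side="left") + 1
    if breaks.direction is Direction.LOW_IS_GOOD:
        bins = 5 - bins
    out[ok] = bins
    return out


def assign_class(value: float, breaks: ClassBreaks) -> int:
    """Class 1-4 for a single value (see :func:`assign_classes`)."""
    if value is None or not np.isfinite(value):
        raise UsageError("assign_class: missing value has no class; exclude it")
    return int(assign_classes(np.asarray([value]), breaks)[0])


_VALID_CLASSES = frozenset((1, 2, 3, 4))
Pair = tuple[int, int]


@dataclass(frozen=True)
class RuleSet:
    """Class-pair to spot-category mapping for one environmental combination.

    ``sour_pairs``/``risky_pairs``/``sweet_pairs`` are explicit ordered
    (class_first, class_second) pairs; every other pair is MEDIUM.  Pairs
    are ordered as (var_first, var_second), and symmetric entries are
    stored explicitly so asymmetric rules (the walkability-NO2 risky cell
    (4, 1)) stay representable.
    """

    name: str
    var_first: str
    var_second: str
    sour_pairs: frozenset[Pair]
    risky_pairs: frozenset[Pair] = frozenset()
    sweet_pairs: frozenset[Pair] = frozenset()

    def __post_init__(self) -> None:
        sets = {
            "sour": self.sour_pairs,
            "risky": self.risky_pairs,
            "sweet": self.sweet_pairs,
        }
        for label, pairs in sets.items():
            for pair in pairs:
                if not (pair[0] in _VALID_CLASSES and pair[1] in _VALID_CLASSES):
                    raise ValidationError(
                        f"ruleset {self.name!r}: {label} pair {pair} outside 1-4"
                    )
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                overlap = sets[a] & sets[b]
                if overlap:
                    raise ValidationError(
                        f"ruleset {self.name!r}: pairs {sorted(overlap)} in "
                        f"both {a} and {b}"
                    )

    def label(self, class_first: int, class_second: int) -> SpotCategory:
        if class_first not in _VALID_CLASSES or class_second not in _VALID_CLASSES:
            raise UsageError(
                f"classes must be in 1-4, got ({class_first}, {class_second})"
            )
        pair = (class_first, class_second)
        if pair in self.sour_pairs:
            return SpotCategory.SOUR
        if pair in self.risky_pairs:
            return SpotCategory.RISKY
        if pair in self.sweet_pairs:
            return SpotCategory.SWEET
        return SpotCategory.MEDIUM


def classify_pair(
    class_first: int, class_second: int, rules: RuleSet
) -> SpotCategory:
    """Spot category for one ordered pair of classes under a rule set."""
    return rules.label(class_first, class_second)


# The six default combinations.  Burden-benefit rationales:
#   1. walkability x NO2      - walking in polluted air raises intake (risky cell)
#   2. heat x NO2             - co-exposure compounds mortality risk (wide sour)
#   3. vegetation x NO2       - greenery mitigates pollution (wide sweet)
#   4. vegetation x heat      - shading/cooling mitigates heat (wide sweet)
#   5. walkability x park/water access - walkability enables access (wide sour+sweet)
#   6. heat x park/water access       - access tempers heat harm (wide sour)
_SYM_LOW = frozenset({(1, 1), (1, 2), (2, 1)})
_SYM_HIGH = frozenset({(4, 4), (3, 4), (4, 3)})


def builtin_rulesets() -> tuple[RuleSet, ...]:
    """The six validated default combinations over the study variables."""
    return (
        RuleSet(
            "walkability_no2",
            "walkability",
            "no2",
            sour_pairs=frozenset({(1, 1)}),
            risky_pairs=frozenset({(4, 1)}),
            sweet_pairs=frozenset({(4, 4)}),
        ),
        RuleSet(
            "heat_no2",
            "heat",
            "no2",
            sour_pairs=_SYM_LOW,
            sweet_pairs=frozenset({(4, 4)}),
        ),
        RuleSet(
            "ndvi_no2",
            "ndvi",
            "no2",
            sour_pairs=frozenset({(1, 1)}),
            sweet_pairs=_SYM_HIGH,
        ),
        RuleSet(
            "ndvi_heat",
            "ndvi",
            "heat",
            sour_pairs=frozenset({(1, 1)}),
            sweet_pairs=_SYM_HIGH,
        ),
        RuleSet(
            "walkability_park",
            "walkability",
            "park_distance",
            sour_pairs=_SYM_LOW,
            sweet_pairs=_SYM_HIGH,
        ),
        RuleSet(
            "heat_park",
            "heat",
            "park_distance",
            sour_pairs=_SYM_LOW,
            sweet_pairs=frozenset({(4, 4)}),
        ),
    )


def rulesets_from_config(source: str | Path | Mapping) -> tuple[RuleSet, ...]:
    """Load rule sets from a YAML/JSON config (or an already-parsed mapping).

    Format::

        rulesets:
          - name: walkability_no2
            var_first: walkability
            var_second: no2
            sour: [[1, 1]]
            risky: [[4, 1]]
            sweet: [[4, 4]]
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        with open(path, encoding="utf-8") as fh:
            raw = (
                yaml.safe_load(fh)
                if path.suffix in {".yml", ".yaml"}
                else json.load(fh)
            )
    else:
        raw = source
    try:
        entries = raw["rulesets"]
    except (KeyError, TypeError) as exc:
        raise FormatError("ruleset config needs a top-level 'rulesets' list") from exc

    def pairs(entry: Mapping, key: str) -> frozenset[Pair]:
        return frozenset((int(a), int(b)) for a, b in entry.get(key, []))

    return tuple(
        RuleSet(
            name=e["name"],
            var_first=e["var_first"],
            var_second=e["var_second"],
            sour_pairs=pairs(e, "sour"),
            risky_pairs=pairs(e, "risky"),
            sweet_pairs=pairs(e, "sweet"),
        )
        for e in entries
    )


@dataclass
class SpotAssignment:
    """Spot labels for every DA classifiable under one combination.

    ``frame`` is indexed by da_id with columns ``class_first``,
    ``class_second``, ``code`` (1-4) and ``category`` (name string); only
    DAs with both variables non-missing appear.
    """

    combination: str
    frame: pd.DataFrame
    rules: RuleSet
    method: BreakMethod
    breaks_first: ClassBreaks | None = None
    breaks_second: ClassBreaks | None = None

    @property
    def n_classified(self) -> int:
        return len(self.frame)

    @property
    def codes(self) -> pd.Series:
        return self.frame["code"]

    @property
    def categories(self) -> pd.Series:
        return self.frame["code"].map(SpotCategory)


def classify_table(
    table: DATable, rules: RuleSet, method: BreakMethod = BreakMethod.QUARTILE
) -> SpotAssignment:
    """Classify every DA of a table under one combination's rule set.

    Breaks are computed per variable over all DAs with that variable
    present; DAs missing either variable of the combination are excluded
    (and logged), not imputed.
    """
    method = BreakMethod(method)
    breaks_first = compute_breaks(table, rules.var_first, method)
    breaks_second = compute_breaks(table, rules.var_second, method)
    v1 = table.env(rules.var_first)
    v2 = table.env(rules.var_second)
    mask = v1.notna() & v2.notna()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info(
            "classify_table(%s): excluded %d DA(s) missing %s or %s",
            rules.name,
            n_dropped,
            rules.var_first,
            rules.var_second,
        )
    c1 = assign_classes(v1[mask], breaks_first)
    c2 = assign_classes(v2[mask], breaks_second)
    lookup = np.empty((5, 5), dtype=int)
    for a in range(1, 5):
        for b in range(1, 5):
            lookup[a, b] = int(rules.label(a, b))
    codes = lookup[c1, c2]
    frame = pd.DataFrame(
        {
            "class_first": c1,
            "class_second": c2,
            "code": codes,
            "category": [SpotCategory(c).name for c in codes],
        },
        index=v1.index[mask],
    )
    frame.index.name = "da_id"
    return SpotAssignment(
        combination=rules.name,
        frame=frame,
        rules=rules,
        method=method,
        breaks_first=breaks_first,
        breaks_second=breaks_second,
    )


def count_spots(assignments: Iterable[SpotAssignment]) -> pd.DataFrame:
    """Per-DA spot counts across combinations (the heat-map table).

    Returns a frame indexed by da_id with columns ``sweet_count``,
    ``sour_count``, ``risky_count``, ``medium_count``; each DA's counts sum
    to the number of combinations in which it was classified.
    """
    assignments = list(assignments)
    cols = ["sweet_count", "sour_count", "risky_count", "medium_count"]
    order = {
        SpotCategory.SWEET: "sweet_count",
        SpotCategory.SOUR: "sour_count",
        SpotCategory.RISKY: "risky_count",
        SpotCategory.MEDIUM: "medium_count",
    }
    if not assignments:
        empty = pd.DataFrame(columns=cols)
        empty.index.name = "da_id"
        return empty
    all_ids = sorted(set().union(*(set(a.frame.index) for a in assignments)))
    out = pd.DataFrame(0, index=pd.Index(all_ids, name="da_id"), columns=cols)
    for a in assignments:
        for cat, col in order.items():
            hit = a.frame.index[a.frame["code"] == int(cat)]
            out.loc[hit, col] += 1
    return out


def spot_proportions(assignment: SpotAssignment) -> dict[SpotCategory, float]:
    """Percentage of classified DAs in each category (sums to 100)."""
    n = assignment.n_classified
    if n == 0:
        raise UndefinedResultError(
            f"spot_proportions: no DAs classified for {assignment.combination!r}"
        )
    counts = assignment.frame["code"].value_counts()
    return {
        cat: 100.0 * float(counts.get(int(cat), 0)) / n for cat in SpotCategory
    }
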
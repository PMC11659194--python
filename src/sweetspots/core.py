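"""DA-level data model, CSV/GeoJSON readers and writers, and two-year alignment.

The unit of analysis is the census dissemination area (DA), the finest
Canadian census geography with public demographic data (roughly 400-700
residents).  A :class:`DATable` holds one census year of DA records:
environmental exposure values, demographic group percentages on the 0-100
scale, and population counts.  Environmental variables are declared in a
:class:`VariableRegistry` so each one carries its unit and the direction
that is favorable to health (e.g. low NO2 is good, high walkability is
good); that direction drives the class ranking downstream.

DA identifiers are opaque strings throughout: Canadian DAUIDs look numeric
but carry leading zeros that must survive a round-trip through CSV.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

logger = logging.getLogger("sweetspots")

__all__ = [
    "SweetspotsError",
    "FormatError",
    "ValidationError",
    "UsageError",
    "DegenerateVariableError",
    "UndefinedResultError",
    "Direction",
    "VariableSpec",
    "VariableRegistry",
    "default_registry",
    "DARecord",
    "DATable",
    "YearPair",
    "read_da_table",
    "write_da_table",
    "attach_geometry",
    "align_years",
]


class SweetspotsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SweetspotsError):
    """An input file does not have the expected structure."""


class ValidationError(SweetspotsError):
    """Input values violate a documented invariant (e.g. a percentage > 100)."""


class UsageError(SweetspotsError):
    """The caller combined operations or arguments incorrectly."""


class DegenerateVariableError(SweetspotsError):
    """A variable cannot be discretized (e.g. all values identical)."""


class UndefinedResultError(SweetspotsError):
    """The requested statistic is undefined on this input (e.g. empty group)."""


class Direction(str, Enum):
    """Which end of a variable's range is favorable to health."""

    HIGH_IS_GOOD = "high_is_good"
    LOW_IS_GOOD = "low_is_good"


@dataclass(frozen=True)
class VariableSpec:
    """An environmental variable with its unit and favorable direction."""

    name: str
    unit: str
    direction: Direction

    def __post_init__(self) -> None:
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))


class VariableRegistry(Mapping):
    """Name-keyed collection of :class:`VariableSpec`, loadable from YAML/JSON.

    Config format::

        variables:
          - {name: no2, unit: ppb, direction: low_is_good}
          - {name: walkability, unit: index, direction: high_is_good}
    """

    def __init__(self, specs: Iterable[VariableSpec] = ()) -> None:
        self._specs: dict[str, VariableSpec] = {}
        for spec in specs:
            self.add(spec)

    def add(self, spec: VariableSpec) -> None:
        if spec.name in self._specs:
            raise ValidationError(f"duplicate variable name in registry: {spec.name!r}")
        self._specs[spec.name] = spec

    def __getitem__(self, name: str) -> VariableSpec:
        return self._specs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    @property
    def names(self) -> list[str]:
        return list(self._specs)

    @classmethod
    def from_config(cls, path: str | Path) -> "VariableRegistry":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        try:
            entries = raw["variables"]
        except (KeyError, TypeError) as exc:
            raise FormatError(f"{path}: expected a top-level 'variables' list") from exc
        return cls(
            VariableSpec(e["name"], e.get("unit", ""), Direction(e["direction"]))
            for e in entries
        )

    def to_config(self, path: str | Path) -> None:
        payload = {
            "variables": [
                {"name": s.name, "unit": s.unit, "direction": s.direction.value}
                for s in self._specs.values()
            ]
        }
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            if path.suffix in {".yml", ".yaml"}:
                yaml.safe_dump(payload, fh, sort_keys=False)
            else:
                json.dump(payload, fh, indent=2)


def default_registry() -> VariableRegistry:
    """Registry for the five study variables.

    NO2 (traffic-related air pollution marker), July mean daily-maximum
    apparent temperature (Humidex heat stress) and distance to the nearest
    park or water body are burdens, so low values are favorable; the
    active-living walkability index and NDVI vegetation coverage are
    benefits, so high values are favorable.
    """
    return VariableRegistry(
        [
            VariableSpec("no2", "ppb", Direction.LOW_IS_GOOD),
            VariableSpec("walkability", "index", Direction.HIGH_IS_GOOD),
            VariableSpec("ndvi", "unitless", Direction.HIGH_IS_GOOD),
            VariableSpec("heat", "degC", Direction.LOW_IS_GOOD),
            VariableSpec("park_distance", "m", Direction.LOW_IS_GOOD),
        ]
    )


@dataclass
class DARecord:
    """One dissemination area in one census year (a row view of a table)."""

    da_id: str
    year: int
    env: dict[str, float]
    demo: dict[str, float]
    population: float
    geometry: Any | None = None


class DATable:
    """All DA records for a single census year, plus the variable registry.

    Backed by a :class:`pandas.DataFrame` indexed by ``da_id`` (string).
    Environmental columns are those whose names appear in the registry;
    demographic columns hold group percentages on the 0-100 scale.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        year: int,
        registry: VariableRegistry,
        demo_groups: Iterable[str] = (),
        geometry: Mapping[str, Any] | None = None,
        provenance: dict | None = None,
    ) -> None:
        df = df.copy()
        df.index = df.index.astype(str)
        if df.index.name != "da_id":
            df.index.name = "da_id"
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate da_id values: {dupes[:5]}")
        self.df = df
        self.year = int(year)
        self.registry = registry
        self.demo_groups = [g for g in demo_groups]
        self.geometry = dict(geometry) if geometry else {}
        self.provenance = provenance or {}
        self._validate()

    def _validate(self) -> None:
        for group in self.demo_groups:
            if group not in self.df.columns:
                raise ValidationError(f"demographic column {group!r} missing from table")
            col = self.df[group]
            bad = col[(col < 0) | (col > 100)]
            if not bad.empty:
                da = bad.index[0]
                raise ValidationError(
                    f"percentage outside [0, 100] for group {group!r} "
                    f"at da_id {da!r}: {bad.iloc[0]!r}"
                )
        if "population" in self.df.columns:
            pop = self.df["population"]
            bad = pop[pop < 0]
            if not bad.empty:
                raise ValidationError(
                    f"negative population at da_id {bad.index[0]!r}"
                )

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def da_ids(self) -> pd.Index:
        return self.df.index

    @property
    def env_vars(self) -> list[str]:
        return [v for v in self.registry.names if v in self.df.columns]

    def env(self, variable: str) -> pd.Series:
        if variable not in self.registry:
            raise UsageError(f"variable {variable!r} not in registry")
        if variable not in self.df.columns:
            raise UsageError(f"variable {variable!r} not present in table")
        return self.df[variable]

    def demo(self, group: str) -> pd.Series:
        if group not in self.demo_groups:
            raise UsageError(f"group {group!r} not a demographic column of this table")
        return self.df[group]

    @property
    def population(self) -> pd.Series:
        if "population" not in self.df.columns:
            raise UsageError("table has no population column")
        return self.df["population"]

    def records(self) -> Iterator[DARecord]:
        env_vars = self.env_vars
        for da_id, row in self.df.iterrows():
            yield DARecord(
                da_id=da_id,
                year=self.year,
                env={v: row[v] for v in env_vars},
                demo={g: row[g] for g in self.demo_groups},
                population=row.get("population", float("nan")),
                geometry=self.geometry.get(da_id),
            )

    def copy(self) -> "DATable":
        return DATable(
            self.df,
            self.year,
            self.registry,
            self.demo_groups,
            self.geometry,
            dict(self.provenance),
        )

    def __repr__(self) -> str:
        return (
            f"DATable(year={self.year}, n={self.n}, "
            f"env={self.env_vars}, demo={self.demo_groups})"
        )


@dataclass(frozen=True)
class YearPair:
    """Two aligned census years and the DA ids present in both.

    Between-year comparisons of spatial pattern are restricted to
    ``common_ids``; within-year metrics always use each table in full.
    """

    table_a: DATable
    table_b: DATable
    common_ids: frozenset[str]

    def __post_init__(self) -> None:
        ids_a = set(self.table_a.da_ids)
        ids_b = set(self.table_b.da_ids)
        if not self.common_ids <= ids_a or not self.common_ids <= ids_b:
            raise ValidationError("common_ids must be a subset of both tables' ids")


def read_da_table(
    path: str | Path,
    year: int,
    registry: VariableRegistry,
    demo_columns: Iterable[str] | None = None,
) -> DATable:
    """Read a one-year DA table from CSV.

    The CSV must have a ``da_id`` column.  Columns named in the registry are
    environmental variables; a ``population`` column, if present, holds
    counts; by default every other column is treated as a demographic
    percentage (pass ``demo_columns`` to restrict).  Rows whose ``da_id`` is
    empty are rejected with a warning; missing values elsewhere are kept as
    missing — DAs with partial data are excluded per combination downstream,
    never imputed.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"da_id": str})
    if "da_id" not in df.columns:
        raise FormatError(f"{path}: no 'da_id' column")
    bad_id = df["da_id"].isna() | (df["da_id"].str.strip() == "")
    if bad_id.any():
        warnings.warn(
            f"{path}: rejected {int(bad_id.sum())} row(s) with unparseable da_id",
            stacklevel=2,
        )
        df = df[~bad_id]
    df = df.set_index("da_id")
    if demo_columns is None:
        demo_columns = [
            c for c in df.columns if c not in registry and c != "population"
        ]
    return DATable(df, year=year, registry=registry, demo_groups=demo_columns)


def write_da_table(table: DATable, path: str | Path) -> None:
    """Write a DA table back to CSV (inverse of :func:`read_da_table`)."""
    table.df.to_csv(Path(path), index=True)


def attach_geometry(
    table: DATable, geojson_path: str | Path, id_property: str = "da_id"
) -> DATable:
    """Attach DA polygons from a GeoJSON FeatureCollection keyed by da_id.

    Geometry is optional everywhere in the pipeline; classification and the
    inequity metrics are purely tabular.  Coordinates are assumed already
    projected to planar meters.
    """
    from shapely.geometry import shape

    with open(geojson_path, encoding="utf-8") as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise FormatError(f"{geojson_path}: expected a GeoJSON FeatureCollection")
    geoms: dict[str, Any] = {}
    for feature in collection.get("features", []):
        props = feature.get("properties") or {}
        if id_property not in props:
            raise FormatError(
                f"{geojson_path}: feature missing {id_property!r} property"
            )
        geoms[str(props[id_property])] = shape(feature["geometry"])
    out = table.copy()
    out.geometry = geoms
    return out


def align_years(table_a: DATable, table_b: DATable) -> YearPair:
    """Pair two census years on the DA ids that exist in both.

    The inputs are left unmodified.  DA boundaries shift slightly between
    censuses; between-year spatial comparisons therefore use only the
    intersection of id sets, while within-year statistics keep every DA.
    """
    if table_a.year == table_b.year:
        raise UsageError(
            f"align_years needs two distinct census years, got {table_a.year} twice"
        )
    common = frozenset(table_a.da_ids) & frozenset(table_b.da_ids)
    if not common:
        warnings.warn(
            "align_years: no DA ids shared between the two years", stacklevel=2
        )
    logger.info(
        "aligned years %s and %s: %d common DAs",
        table_a.year,
        table_b.year,
        len(common),
    )
    return YearPair(table_a=table_a, table_b=table_b, common_ids=common)
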
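"""Exposure quantities computed by the pipeline itself.

Four operations: the Humidex apparent temperature (heat stress), Euclidean
accessibility to parks and water bodies, postal-code-to-DA mean
aggregation, and population-weighted group means of any variable.

All geometry is assumed to be in a planar, meter-based coordinate system;
reprojection is the caller's job.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .core import DATable, SweetspotsError, UndefinedResultError, UsageError

logger = logging.getLogger("sweetspots")

__all__ = [
    "TemperaturePair",
    "PointSite",
    "vapor_pressure",
    "humidex",
    "nearest_distance",
    "read_point_sites",
    "aggregate_to_da",
    "population_weighted_mean",
]

# Environment Canada Humidex constants: saturation vapor pressure at the
# dew point via the Clausius-Clapeyron form anchored at the triple point.
_E0_HPA = 6.11
_CC_K = 5417.7530
_T_TRIPLE_K = 273.16
_HUMIDEX_COEF = 0.5555
_REFERENCE_E_HPA = 10.0


@dataclass(frozen=True)
class TemperaturePair:
    """Air temperature and dew point in degrees Celsius."""

    air_temp: float
    dew_point: float


def vapor_pressure(dew_point: float | np.ndarray) -> float | np.ndarray:
    """Water vapor pressure (hPa) at the given dew point (degC)."""
    dew_k = np.asarray(dew_point, dtype=float) + 273.15
    e = _E0_HPA * np.exp(_CC_K * (1.0 / _T_TRIPLE_K - 1.0 / dew_k))
    return float(e) if np.isscalar(dew_point) else e


def humidex(
    air_temp: float | np.ndarray | TemperaturePair,
    dew_point: float | np.ndarray | None = None,
) -> float | np.ndarray:
    """Humidex apparent temperature (degC) from air temperature and dew point.

        H = T + 0.5555 * (e - 10)

    with the vapor pressure ``e`` (hPa) computed from the dew point.  When
    ``e`` is exactly 10 hPa the humidity correction vanishes and H equals
    the air temperature; drier air gives H below T with a floor of
    T - 5.555, and humid air pushes H above T.  Accepts a
    :class:`TemperaturePair` or separate scalars/arrays.
    """
    if isinstance(air_temp, TemperaturePair):
        pair = air_temp
        air_temp, dew_point = pair.air_temp, pair.dew_point
    if dew_point is None:
        raise UsageError("humidex needs both an air temperature and a dew point")
    t = np.asarray(air_temp, dtype=float)
    td = np.asarray(dew_point, dtype=float)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(td))):
        raise SweetspotsError("humidex: non-finite temperature input")
    if np.any(td > t):
        warnings.warn(
            "dew point exceeds air temperature (supersaturation); "
            "proceeding, but check the inputs",
            stacklevel=2,
        )
    h = t + _HUMIDEX_COEF * (vapor_pressure(td) - _REFERENCE_E_HPA)
    return float(h) if h.ndim == 0 else h


@dataclass(frozen=True)
class PointSite:
    """A postal-code point with planar coordinates (m) and its parent DA."""

    site_id: str
    x: float
    y: float
    parent_da: str | None = None


def nearest_distance(
    site: PointSite | tuple[float, float],
    features: Sequence[BaseGeometry],
) -> float:
    """Minimum Euclidean distance (m) from a site to any feature.

    A point inside or on the boundary of a polygon is at distance 0 — being
    in a park counts as full access.  Polylines and points are handled the
    same way via shapely's distance, which for exterior points equals the
    distance to the feature boundary.
    """
    from shapely.geometry import Point

    if len(features) == 0:
        raise UsageError("nearest_distance: empty feature collection")
    if isinstance(site, PointSite):
        pt = Point(site.x, site.y)
    else:
        pt = Point(*site)
    return min(geom.distance(pt) for geom in features)


def read_point_sites(path: str | Path) -> pd.DataFrame:
    """Read a point-site CSV (site_id, x, y, parent_da, value columns)."""
    df = pd.read_csv(Path(path), dtype={"site_id": str, "parent_da": str})
    required = {"site_id", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise SweetspotsError(f"{path}: missing columns {sorted(missing)}")
    return df


def aggregate_to_da(sites: pd.DataFrame, value_name: str) -> pd.Series:
    """Average a site-level value up to DAs (unweighted arithmetic mean).

    Because each postal code holds a roughly fixed number of households,
    the plain mean over postal codes in a DA approximates a
    population-weighted mean.  Missing site values are skipped; DAs with no
    non-missing sites are absent from the result.
    """
    if "parent_da" not in sites.columns:
        raise UsageError("aggregate_to_da: sites need a parent_da column")
    if value_name not in sites.columns:
        raise UsageError(f"aggregate_to_da: no column {value_name!r}")
    usable = sites.dropna(subset=["parent_da"])
    n_missing = int(usable[value_name].isna().sum())
    if n_missing:
        logger.info(
            "aggregate_to_da(%s): skipped %d missing site value(s)",
            value_name,
            n_missing,
        )
    out = usable.groupby("parent_da")[value_name].mean()
    out = out.dropna()
    out.index.name = "da_id"
    out.name = value_name
    return out


def population_weighted_mean(table: DATable, variable: str, group: str) -> float:
    """Group-exposure mean of a variable, weighting each DA by the group's
    resident count (percentage x DA population / 100).

    DAs missing the variable, the group percentage, or population are
    dropped.  Raises :class:`UndefinedResultError` when the total group
    population over usable DAs is zero.
    """
    values = table.env(variable) if variable in table.registry else table.df[variable]
    group_pop = table.demo(group) * table.population / 100.0
    frame = pd.DataFrame({"v": values, "w": group_pop}).dropna()
    total = frame["w"].sum()
    if total <= 0:
        raise UndefinedResultError(
            f"population_weighted_mean: zero total population for group {group!r}"
        )
    return float((frame["v"] * frame["w"]).sum() / total)
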
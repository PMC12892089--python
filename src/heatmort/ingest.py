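"""Reading, validating and writing the pipeline's input tables.

Three long-format CSV dialects (comma-separated, header row, UTF-8,
ISO-8601 dates):

* daily series — columns ``region_id, date, value`` holding either daily
  mean temperature in °C or daily all-cause death counts;
* official annual counts — columns ``year, count`` plus an optional
  ``region_id`` (absent or ``statewide`` meaning a state total);
* region centroids — columns ``region_id, lat, lon`` in degrees, used to
  assign each region the nearest point of a gridded-temperature lattice.

Validation enforces unique (region, date) keys, non-negative integer
death counts, and per-region date contiguity: after validation every
region carries one row per calendar day of its span, with gaps marked as
explicit missing values rather than absent rows.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_daily_series",
    "write_daily_series",
    "validate_daily_series",
    "read_official_counts",
    "assign_nearest_gridpoint",
    "haversine_km",
]

_EARTH_RADIUS_KM = 6371.0088


def validate_daily_series(df: pd.DataFrame, flavor: str = "temperature") -> pd.DataFrame:
    """Validate a long-format daily series and normalize its dtypes.

    ``flavor`` is ``"temperature"`` (float °C) or ``"deaths"``
    (non-negative integer counts; missing allowed as NaN). Duplicate
    (region_id, date) pairs and negative death counts raise; each
    region's rows are reindexed to a contiguous daily calendar with
    explicit NaN for gaps.
    """
    if flavor not in ("temperature", "deaths"):
        raise ValueError(f"unknown flavor {flavor!r}")
    required = {"region_id", "date", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"daily series missing columns {sorted(missing)}")
    out = df.loc[:, ["region_id", "date", "value"]].copy()
    out["region_id"] = out["region_id"].astype(str)
    try:
        out["date"] = pd.to_datetime(out["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date in daily series: {exc}") from exc

    dup = out.duplicated(subset=["region_id", "date"])
    if dup.any():
        first = out.loc[dup, ["region_id", "date"]].iloc[0]
        raise ValueError(
            "duplicate (region_id, date) pair: "
            f"({first['region_id']!r}, {first['date'].date()})"
        )

    out["value"] = pd.to_numeric(out["value"], errors="raise")
    if flavor == "deaths":
        vals = out["value"].dropna()
        if (vals < 0).any():
            bad = out.loc[out["value"] < 0].iloc[0]
            raise ValueError(
                f"negative death count {bad['value']} for region "
                f"{bad['region_id']!r} on {bad['date'].date()}"
            )
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("death counts must be integers")

    # make gaps explicit: one row per calendar day per region
    pieces = []
    for region, grp in out.groupby("region_id", sort=True):
        grp = grp.sort_values("date").set_index("date")
        full = pd.date_range(grp.index.min(), grp.index.max(), freq="D")
        if len(full) != len(grp):
            warnings.warn(
                f"region {region!r}: {len(full) - len(grp)} missing day(s) "
                "in span; marked as missing",
                stacklevel=2,
            )
        grp = grp.reindex(full)
        grp["region_id"] = region
        pieces.append(grp.rename_axis("date").reset_index())
    result = pd.concat(pieces, ignore_index=True)[["region_id", "date", "value"]]
    return result


def read_daily_series(path: str | Path, flavor: str = "temperature") -> pd.DataFrame:
    """Read and validate a daily-series CSV (see module docstring)."""
    df = pd.read_csv(path)
    return validate_daily_series(df, flavor=flavor)


def write_daily_series(df: pd.DataFrame, path: str | Path) -> None:
    out = df.loc[:, ["region_id", "date", "value"]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_official_counts(path: str | Path) -> pd.DataFrame:
    """Read annual official heat-death counts.

    Returns columns ``region_id`` (``"statewide"`` when absent in the
    file), ``year``, ``count``. Repeated (scope, year) keys and
    non-integer or negative counts raise.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"official counts file {path} is empty", stacklevel=2)
        return pd.DataFrame(columns=["region_id", "year", "count"])
    missing = {"year", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"official counts missing columns {sorted(missing)}")
    out = df.copy()
    if "region_id" not in out.columns:
        out["region_id"] = "statewide"
    out["region_id"] = out["region_id"].astype(str)
    out["year"] = pd.to_numeric(out["year"], errors="raise").astype(int)
    counts = pd.to_numeric(out["count"], errors="raise")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("official counts must be integers")
    if (counts < 0).any():
        raise ValueError("official counts must be non-negative")
    out["count"] = counts.astype(int)
    dup = out.duplicated(subset=["region_id", "year"])
    if dup.any():
        first = out.loc[dup].iloc[0]
        raise ValueError(
            f"repeated official count for ({first['region_id']!r}, {first['year']})"
        )
    return out[["region_id", "year", "count"]]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a spherical Earth (vectorized)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def assign_nearest_gridpoint(
    centroids: pd.DataFrame, lattice: pd.DataFrame
) -> pd.Series:
    """Map each region centroid to its nearest grid point.

    ``centroids`` has columns ``region_id, lat, lon``; ``lattice`` has
    columns ``lat, lon`` (its positional index identifies grid points).
    Nearest means smallest great-circle (haversine) distance; exact ties
    go to the lexicographically smallest (lat, lon) of the tied set.
    Returns a Series region_id → lattice index.
    """
    if lattice.empty:
        raise ValueError("empty grid lattice")
    for name, df in (("centroids", centroids), ("lattice", lattice)):
        lat = np.asarray(df["lat"], dtype=float)
        lon = np.asarray(df["lon"], dtype=float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 360):
            raise ValueError(f"{name}: coordinates outside plausible bounds")
    glat = lattice["lat"].to_numpy(dtype=float)
    glon = lattice["lon"].to_numpy(dtype=float)
    gidx = lattice.index.to_numpy()
    # stable lexicographic order on (lat, lon) so argmin resolves ties
    order = np.lexsort((glon, glat))
    glat_s, glon_s, gidx_s = glat[order], glon[order], gidx[order]
    result = {}
    for _, row in centroids.iterrows():
        d = haversine_km(row["lat"], row["lon"], glat_s, glon_s)
        # distances within a millimetre count as ties -> lexicographic pick
        tied = np.flatnonzero(d <= d.min() + 1e-6)
        result[str(row["region_id"])] = gidx_s[int(tied[0])]
    return pd.Series(result, name="grid_index").rename_axis("region_id")
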
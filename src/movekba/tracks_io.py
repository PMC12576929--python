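"""Track table I/O, great-circle distances and a colony-centred equal-area projection.

Tracks are carried as pandas DataFrames with the canonical columns
``individual_id, colony_id, timestamp, lon, lat`` (WGS84 decimal degrees,
ISO-8601 UTC timestamps).  Planar coordinates are kilometres in a Lambert
azimuthal equal-area plane centred on each colony; equal-area is required
because areas in km² are the headline downstream outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping

logger = logging.getLogger(__name__)

#: Mean Earth radius (IUGG), km.  Fixed so distances are reproducible.
EARTH_RADIUS_KM = 6371.0088

CANONICAL_COLUMNS = ("individual_id", "colony_id", "timestamp", "lon", "lat")


class TrackFormatError(ValueError):
    """Raised when a track table violates the expected format."""


@dataclass(frozen=True)
class ColonySite:
    """A breeding colony: the central place trips start from and return to."""

    colony_id: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(
                f"colony {self.colony_id!r}: coordinates ({self.lon}, {self.lat}) "
                "outside valid WGS84 range"
            )


def read_tracks(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited track table into the canonical frame.

    Parameters
    ----------
    path
        CSV/TSV file with a header.  Required logical columns:
        individual_id, colony_id, timestamp, lon, lat.
    column_map
        Optional mapping from canonical name to the file's column name,
        e.g. ``{"individual_id": "bird", "timestamp": "date_time"}``.
    sep
        Field separator; inferred from the extension when None
        (``.tsv`` → tab, otherwise comma).

    Returns
    -------
    DataFrame sorted by (individual_id, timestamp) with exact-duplicate
    rows dropped (the number dropped is logged).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    colmap = dict(column_map or {})
    rename = {}
    for canon in CANONICAL_COLUMNS:
        source = colmap.get(canon, canon)
        if source not in raw.columns:
            raise TrackFormatError(f"missing required column {source!r} (for {canon!r})")
        rename[source] = canon
    df = raw.rename(columns=rename)[list(CANONICAL_COLUMNS)].copy()

    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
        raise TrackFormatError(
            f"unparsable ISO-8601 timestamp {df.loc[bad, 'timestamp'].iloc[0]!r} "
            f"at line {line}"
        )
    df["timestamp"] = ts
    for col, lo, hi in (("lon", -180.0, 180.0), ("lat", -90.0, 90.0)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < lo) | (vals > hi)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise TrackFormatError(
                f"invalid {col} value {df.loc[bad, col].iloc[0]!r} at line {line}"
            )
        df[col] = vals

    n0 = len(df)
    df = df.drop_duplicates()
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_tracks: dropped %d exact-duplicate rows", dropped)
    df = df.sort_values(["individual_id", "timestamp"], kind="mergesort")
    return df.reset_index(drop=True)


def write_tracks(df: pd.DataFrame, path) -> None:
    """Write the canonical track frame; lossless round-trip with read_tracks."""
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Haversine great-circle distance in km (R = 6371.0088 km).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    return float(d) if np.isscalar(lon1) or d.ndim == 0 else d


def project_local(
    lon, lat, colony: ColonySite, max_range_km: float = 2000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Project WGS84 points to km in a Lambert azimuthal equal-area plane.

    The plane is centred on *colony*, which maps to (0, 0); the y axis
    points true north.  Spherical formulas on R = 6371.0088 km; invertible
    by :func:`unproject_local` to < 1 m at study-relevant ranges.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    dist = great_circle_km(lon, lat, colony.lon, colony.lat)
    too_far = np.asarray(dist) > max_range_km
    if np.any(too_far):
        i = int(np.flatnonzero(np.atleast_1d(too_far))[0])
        raise ValueError(
            f"fix index {i} is {np.atleast_1d(dist)[i]:.1f} km from colony "
            f"{colony.colony_id!r} (limit {max_range_km} km)"
        )
    lam0, phi0 = np.radians(colony.lon), np.radians(colony.lat)
    lam, phi = np.radians(lon), np.radians(lat)
    dl = lam - lam0
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dl)
    kprime = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * kprime * np.cos(phi) * np.sin(dl)
    y = EARTH_RADIUS_KM * kprime * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dl)
    )
    return x, y


def unproject_local(x, y, colony: ColonySite) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_local`: planar km back to (lon, lat) degrees."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    lam0, phi0 = np.radians(colony.lon), np.radians(colony.lat)
    rho = np.hypot(x, y)
    c = 2.0 * np.arcsin(np.minimum(1.0, rho / (2.0 * EARTH_RADIUS_KM)))
    with np.errstate(invalid="ignore"):
        phi = np.arcsin(
            np.cos(c) * np.sin(phi0) + np.where(rho > 0, y * np.sin(c) * np.cos(phi0) / rho, 0.0)
        )
        lam = lam0 + np.arctan2(
            x * np.sin(c),
            rho * np.cos(phi0) * np.cos(c) - y * np.sin(phi0) * np.sin(c),
        )
    at_origin = rho == 0
    phi = np.where(at_origin, phi0, phi)
    lam = np.where(at_origin, lam0, lam)
    return np.degrees(lam), np.degrees(phi)


def add_projected(df: pd.DataFrame, colony: ColonySite) -> pd.DataFrame:
    """Return a copy of *df* with x, y columns (km, colony-centred plane)."""
    out = df.copy()
    x, y = project_local(out["lon"].to_numpy(), out["lat"].to_numpy(), colony)
    out["x"] = x
    out["y"] = y
    return out


def polygons_to_geojson(
    records: Sequence[tuple[object, dict]], path=None
) -> dict:
    """Serialise (shapely geometry, properties) pairs to a GeoJSON FeatureCollection.

    Geometries are expected in WGS84 lon/lat; properties should carry areas
    in km² computed upstream on the equal-area plane.
    """
    features = []
    for geom, props in records:
        features.append(
            {"type": "Feature", "geometry": mapping(geom), "properties": dict(props)}
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def grid_to_csv(x_centres: np.ndarray, y_centres: np.ndarray, values: np.ndarray, path) -> None:
    """Write a gridded surface as long-format CSV (x,y,value); bit-exact round-trip."""
    xx, yy = np.meshgrid(x_centres, y_centres, indexing="ij")
    df = pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(), "value": values.ravel()})
    df.to_csv(path, index=False, float_format="%.17g")


def grid_from_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a long-format grid CSV back to (x_centres, y_centres, values)."""
    df = pd.read_csv(path, float_precision="round_trip")
    x = np.unique(df["x"].to_numpy())
    y = np.unique(df["y"].to_numpy())
    vals = df["value"].to_numpy().reshape(len(x), len(y))
    return x, y, vals
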
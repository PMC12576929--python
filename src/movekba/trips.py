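"""Trip segmentation for central-place foragers.

A trip is an at-sea excursion between colony departure and return.  Fixes
within the 500 m inner buffer of the colony are stationary colony fixes and
are excluded; a trip closes when the bird stays inside the 1 km return
buffer for at least 14 min.  Trailing excursions with no qualifying return
are kept but flagged incomplete so they can be eliminated downstream.
"Within a buffer" is the closed condition distance ≤ radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from movekba.tracks_io import ColonySite, great_circle_km, project_local

logger = logging.getLogger(__name__)


@dataclass
class Trip:
    """One at-sea excursion with its metrics."""

    trip_id: str
    individual_id: str
    colony_id: str
    fixes: pd.DataFrame  # canonical columns + x, y, dist_colony_km
    complete: bool
    total_distance_km: float = field(default=np.nan)
    max_distance_km: float = field(default=np.nan)
    duration_h: float = field(default=np.nan)

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)


def split_trips(
    fixes: pd.DataFrame,
    colony: ColonySite,
    inner_buffer_km: float = 0.5,
    return_buffer_km: float = 1.0,
    min_return_min: float = 14.0,
    min_trip_fixes: int = 5,
    sampling_interval_s: float | None = None,
) -> list[Trip]:
    """Split one individual's time-sorted fix stream into trips.

    Parameters mirror the segmentation rules: *inner_buffer_km* defines
    stationary colony fixes (excluded from trips), *return_buffer_km* and
    *min_return_min* define a qualifying return (the bird stays inside the
    return buffer at least that long).  A single fix inside the return
    buffer counts as one sampling interval of residence.  Trips with fewer
    than *min_trip_fixes* at-sea fixes are discarded (guards against GPS
    jitter around the colony); set to 1 to keep everything.

    Returns trips in temporal order; the trailing excursion is flagged
    ``complete=False`` when the stream ends without a qualifying return.
    Residence duration counts one sampling interval per fix inside the
    return buffer (elapsed span plus one interval), so a single fix inside
    counts as its sampling interval.
    """
    if fixes.empty:
        return []
    ts = pd.to_datetime(fixes["timestamp"], utc=True)
    if not ts.is_monotonic_increasing:
        raise ValueError("fixes must be sorted by timestamp")
    individual_id = str(fixes["individual_id"].iloc[0])

    df = fixes.copy()
    df["timestamp"] = ts
    if "x" not in df.columns or "y" not in df.columns:
        x, y = project_local(df["lon"].to_numpy(), df["lat"].to_numpy(), colony)
        df["x"], df["y"] = x, y
    df["dist_colony_km"] = great_circle_km(
        df["lon"].to_numpy(), df["lat"].to_numpy(), colony.lon, colony.lat
    )

    if sampling_interval_s is None:
        dt = ts.diff().dt.total_seconds().dropna()
        sampling_interval_s = float(dt.median()) if len(dt) else 100.0
    gaps = ts.diff().dt.total_seconds()
    n_long_gaps = int((gaps > 3600).sum())
    if n_long_gaps:
        logger.warning(
            "split_trips(%s): %d inter-fix gaps exceed 1 h", individual_id, n_long_gaps
        )

    trips: list[Trip] = []
    current: list[int] = []  # positional indices of at-sea fixes (d > inner)
    run_start_t = run_end_t = None  # current return-buffer residence run
    dist = df["dist_colony_km"].to_numpy()
    times = df["timestamp"].to_numpy()

    def residence_minutes() -> float:
        # each fix represents one sampling interval, so a run of n fixes
        # counts n intervals (a single fix counts its sampling interval)
        if run_start_t is None:
            return 0.0
        span = (run_end_t - run_start_t) / np.timedelta64(1, "s")
        return (span + sampling_interval_s) / 60.0

    def close(complete: bool) -> None:
        nonlocal current
        if len(current) >= min_trip_fixes:
            sub = df.iloc[current].reset_index(drop=True)
            trips.append(
                Trip(
                    trip_id=f"{individual_id}_t{len(trips):03d}",
                    individual_id=individual_id,
                    colony_id=colony.colony_id,
                    fixes=sub,
                    complete=complete,
                )
            )
        elif current:
            logger.info(
                "split_trips(%s): discarded excursion of %d fixes (< %d)",
                individual_id, len(current), min_trip_fixes,
            )
        current = []

    # residence runs (d <= return buffer) include colony fixes; trip fix
    # lists exclude everything at or under the inner buffer
    for i in range(len(df)):
        if dist[i] <= return_buffer_km:
            if run_start_t is None:
                run_start_t = times[i]
            run_end_t = times[i]
            if dist[i] > inner_buffer_km:
                current.append(i)
        else:
            if run_start_t is not None and residence_minutes() >= min_return_min:
                # the residence run that just ended was a qualifying return
                close(complete=True)
            current.append(i)
            run_start_t = run_end_t = None
    if current:
        qualified = run_start_t is not None and residence_minutes() >= min_return_min
        close(complete=bool(qualified))

    for trip in trips:
        if trip.n_fixes >= 2:
            m = trip_metrics(trip, colony)
            trip.total_distance_km = m["total_distance_km"]
            trip.max_distance_km = m["max_distance_km"]
            trip.duration_h = m["duration_h"]
    return trips


def filter_complete(trips: list[Trip]) -> list[Trip]:
    """Keep only complete trips (bird returned to the colony); order preserved."""
    kept = [t for t in trips if t.complete]
    removed = len(trips) - len(kept)
    if removed:
        logger.info("filter_complete: removed %d incomplete trips", removed)
    return kept


def trip_metrics(trip: Trip, colony: ColonySite | None = None) -> dict:
    """Total path distance, max distance from colony, duration and fix count."""
    fx = trip.fixes
    if len(fx) < 2:
        raise ValueError("trip metrics need at least 2 fixes")
    lon = fx["lon"].to_numpy()
    lat = fx["lat"].to_numpy()
    total = float(np.sum(great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])))
    if colony is not None:
        dist_col = great_circle_km(lon, lat, colony.lon, colony.lat)
    else:
        dist_col = fx["dist_colony_km"].to_numpy()
    ts = pd.to_datetime(fx["timestamp"], utc=True)
    duration_h = float((ts.iloc[-1] - ts.iloc[0]).total_seconds() / 3600.0)
    return {
        "total_distance_km": total,
        "max_distance_km": float(np.max(dist_col)),
        "duration_h": duration_h,
        "n_fixes": len(fx),
    }


def filter_colonies(
    trips: list[Trip],
    tagging_years: pd.DataFrame | None = None,
    min_individuals: int = 8,
    min_per_year: int = 3,
) -> tuple[set[str], pd.DataFrame]:
    """Apply the colony inclusion rules.

    A colony is retained iff it has at least *min_individuals* individuals
    with ≥ 1 complete trip AND every represented tagging year has at least
    *min_per_year* tagged individuals.  Tagging year is taken from
    *tagging_years* (columns individual_id, colony_id, year) when given,
    otherwise from each individual's first fix timestamp.

    Returns (retained colony ids, per-colony summary frame).
    """
    complete = [t for t in trips if t.complete]
    if tagging_years is None:
        recs = []
        for t in complete:
            year = pd.to_datetime(t.fixes["timestamp"].iloc[0], utc=True).year
            recs.append((t.individual_id, t.colony_id, year))
        tagging_years = pd.DataFrame(
            recs, columns=["individual_id", "colony_id", "year"]
        ).drop_duplicates()

    by_colony = {}
    for t in complete:
        by_colony.setdefault(t.colony_id, set()).add(t.individual_id)

    rows = []
    retained: set[str] = set()
    for colony_id, individuals in sorted(by_colony.items()):
        yr = tagging_years[tagging_years["colony_id"] == colony_id]
        per_year = yr.groupby("year")["individual_id"].nunique()
        ok_n = len(individuals) >= min_individuals
        ok_years = bool((per_year >= min_per_year).all()) if len(per_year) else False
        if ok_n and ok_years:
            retained.add(colony_id)
        rows.append(
            {
                "colony_id": colony_id,
                "n_individuals": len(individuals),
                "min_individuals_per_year": int(per_year.min()) if len(per_year) else 0,
                "retained": ok_n and ok_years,
            }
        )
        if not (ok_n and ok_years):
            logger.info(
                "filter_colonies: excluded %s (n=%d, min/year=%s)",
                colony_id, len(individuals),
                int(per_year.min()) if len(per_year) else "NA",
            )
    return retained, pd.DataFrame(rows)


def interpolate_track(fixes: pd.DataFrame, interval_s: float = 100.0) -> pd.DataFrame:
    """Linearly interpolate projected positions onto a regular time grid.

    Grid points are exact multiples of *interval_s* from the first fix; no
    extrapolation beyond the last fix.  Used only for the sensitivity check
    that regularising the nominal GPS duty cycle changes little.
    """
    if len(fixes) < 2:
        raise ValueError("interpolation needs at least 2 fixes")
    ts = pd.to_datetime(fixes["timestamp"], utc=True)
    t = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    grid = np.arange(0.0, t[-1] + 1e-9, interval_s)
    x = np.interp(grid, t, fixes["x"].to_numpy())
    y = np.interp(grid, t, fixes["y"].to_numpy())
    out = pd.DataFrame(
        {
            "timestamp": ts.iloc[0] + pd.to_timedelta(grid, unit="s"),
            "x": x,
            "y": y,
        }
    )
    for col in ("individual_id", "colony_id"):
        if col in fixes.columns:
            out[col] = fixes[col].iloc[0]
    return out


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    """Tidy per-trip metric table (one row per trip)."""
    rows = [
        {
            "trip_id": t.trip_id,
            "individual_id": t.individual_id,
            "colony_id": t.colony_id,
            "complete": t.complete,
            "n_fixes": t.n_fixes,
            "total_distance_km": t.total_distance_km,
            "max_distance_km": t.max_distance_km,
            "duration_h": t.duration_h,
        }
        for t in trips
    ]
    return pd.DataFrame(rows)
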
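"""Colony-based trip delineation, classification and metrics.

A candidate trip is a maximal run of consecutive retained fixes beyond the
inner colony buffer (default 20 km). Two categories are recognised:

* ``short_neglect`` — brief daytime excursions (<= 24 h) by incubating
  adults leaving the egg unattended, optionally confirmed by nest
  attendance records;
* ``long`` — multi-day foraging trips containing more than five fixes
  beyond the buffer.

Trips matching neither rule are tagged ``unclassified`` and excluded from
metric comparisons. A trip is complete when a later fix returns to within
the 30-km return buffer of the colony.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geotrack import (
    Colony,
    DegenerateTrackError,
    Track,
    haversine_km,
    initial_bearing_deg,
)
from . import seastats

CATEGORY_SHORT_NEGLECT = "short_neglect"
CATEGORY_LONG = "long"
CATEGORY_UNCLASSIFIED = "unclassified"


@dataclass
class Trip:
    """A colony-to-colony excursion (the beyond-buffer run of fixes)."""

    deployment_id: str
    bird_id: str
    sex: str
    season: str
    stage: str
    year: int
    fixes: pd.DataFrame  # timestamp, lon, lat, dist_km (to colony)
    complete: bool
    category: str | None = None
    trip_id: str = ""

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def duration_h(self) -> float:
        ts = self.fixes["timestamp"]
        return float((ts.iloc[-1] - ts.iloc[0]).total_seconds() / 3600.0)


@dataclass(frozen=True)
class TripMetrics:
    duration_h: float
    max_range_km: float
    total_distance_km: float
    bearing_deg: float


def split_trips(
    track: Track,
    colony: Colony,
    inner_buff_km: float = 20.0,
    min_locs: int = 6,
    return_buff_km: float = 30.0,
) -> list[Trip]:
    """Delineate candidate trips from a filtered track.

    Returns uncategorized trips (``category=None``); a track that never
    leaves the inner buffer yields an empty list. Completeness requires a
    subsequent fix within ``return_buff_km`` of the colony.
    """
    df = track.retained().copy()
    df["dist_km"] = haversine_km(df["lon"], df["lat"], colony.point.lon, colony.point.lat)
    outside = (df["dist_km"] > inner_buff_km).to_numpy()
    if not outside.any():
        return []

    # maximal runs of consecutive outside fixes
    edges = np.flatnonzero(np.diff(np.concatenate(([0], outside.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]

    near_return = (df["dist_km"] <= return_buff_km).to_numpy()
    trips: list[Trip] = []
    for k, (a, b) in enumerate(zip(starts, stops)):
        complete = bool(near_return[b:].any())
        trips.append(
            Trip(
                deployment_id=track.deployment_id,
                bird_id=track.bird_id,
                sex=track.sex,
                season=track.season,
                stage=track.stage,
                year=track.year,
                fixes=df.iloc[a:b].reset_index(drop=True),
                complete=complete,
                trip_id=f"{track.deployment_id}_t{k:02d}",
            )
        )
    return trips


def classify_trip(
    trip: Trip,
    attendance: pd.DataFrame | None = None,
    min_locs: int = 6,
    neglect_max_h: float = 24.0,
) -> str:
    """Assign the trip category and return it.

    ``attendance`` (optional) has columns ``deployment-id``, ``date``,
    ``on-duty``; when provided, a short neglect trip additionally requires
    an on-duty record for the departure date.
    """
    on_duty = True
    if attendance is not None:
        day = trip.fixes["timestamp"].iloc[0].date()
        rows = attendance[
            (attendance["deployment-id"].astype(str) == trip.deployment_id)
            & (pd.to_datetime(attendance["date"]).dt.date == day)
        ]
        on_duty = bool(len(rows)) and bool(rows["on-duty"].iloc[0])

    if trip.stage == "incubation" and trip.duration_h <= neglect_max_h and on_duty:
        trip.category = CATEGORY_SHORT_NEGLECT
    elif len(trip) >= min_locs:
        trip.category = CATEGORY_LONG
    else:
        trip.category = CATEGORY_UNCLASSIFIED
    return trip.category


def trip_metrics(trip: Trip, colony: Colony) -> TripMetrics:
    """Duration, cumulative travel distance, maximum colony range and the
    great-circle bearing from the colony to the most distal fix (ties
    resolved to the earlier fix)."""
    df = trip.fixes
    if len(df) < 2:
        raise DegenerateTrackError(f"trip {trip.trip_id}: needs >= 2 fixes for metrics")
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    seg = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    ranges = haversine_km(lon, lat, colony.point.lon, colony.point.lat)
    i_max = int(np.argmax(ranges))  # argmax returns first (earliest) maximum
    bearing = float(
        initial_bearing_deg(colony.point.lon, colony.point.lat, lon[i_max], lat[i_max])
    )
    return TripMetrics(
        duration_h=trip.duration_h,
        max_range_km=float(ranges.max()),
        total_distance_km=float(seg.sum()),
        bearing_deg=bearing,
    )


def trips_table(trips: list[Trip], colony: Colony) -> pd.DataFrame:
    """One row per trip with metadata, category, completeness and metrics."""
    rows = []
    for tr in trips:
        m = trip_metrics(tr, colony)
        rows.append(
            {
                "trip_id": tr.trip_id,
                "deployment_id": tr.deployment_id,
                "bird_id": tr.bird_id,
                "sex": tr.sex,
                "season": tr.season,
                "stage": tr.stage,
                "year": tr.year,
                "category": tr.category,
                "complete": tr.complete,
                "n_fixes": len(tr),
                "duration_h": m.duration_h,
                "max_range_km": m.max_range_km,
                "total_distance_km": m.total_distance_km,
                "bearing_deg": m.bearing_deg,
            }
        )
    return pd.DataFrame(rows)


def trip_summary_table(
    trips: list[Trip], colony: Colony, strata: list[tuple] | None = None
) -> pd.DataFrame:
    """Per season x stage x category summary of trip metrics.

    Mean +- SD, min and max per metric, bird and trip counts, and the
    circular mean direction (with circular SD) of trip bearings. When a
    fixed layout of ``(season, stage, category)`` strata is requested,
    empty strata are emitted with n = 0 and blank statistics.
    """
    table = trips_table([t for t in trips if t.category != CATEGORY_UNCLASSIFIED], colony)
    if table.empty and strata is None:
        return pd.DataFrame()
    out = []
    for (season, stage, category), grp in table.groupby(
        ["season", "stage", "category"], sort=True
    ):
        row: dict = {
            "season": season,
            "stage": stage,
            "category": category,
            "n_birds": grp["bird_id"].nunique(),
            "n_trips": len(grp),
        }
        for metric in ("duration_h", "max_range_km", "total_distance_km"):
            v = grp[metric]
            row[f"{metric}_mean"] = v.mean()
            row[f"{metric}_sd"] = v.std(ddof=1) if len(v) > 1 else 0.0
            row[f"{metric}_min"] = v.min()
            row[f"{metric}_max"] = v.max()
        mean_dir, rbar = seastats.circular_mean(grp["bearing_deg"].to_numpy())
        row["direction_mean_deg"] = mean_dir
        row["direction_sd_deg"] = seastats.circular_sd_deg(rbar)
        out.append(row)
    result = pd.DataFrame(out)
    if strata is not None:
        seen = set(map(tuple, result[["season", "stage", "category"]].to_numpy())) if len(result) else set()
        blanks = [
            {"season": s, "stage": st, "category": c, "n_birds": 0, "n_trips": 0}
            for (s, st, c) in strata
            if (s, st, c) not in seen
        ]
        if blanks:
            result = pd.concat([result, pd.DataFrame(blanks)], ignore_index=True)
        result = result.sort_values(["season", "stage", "category"]).reset_index(drop=True)
    return result
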
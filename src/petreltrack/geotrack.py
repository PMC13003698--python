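"""Core telemetry plumbing: domain types, Movebank-style track I/O, spherical
geodesy, the colony-centred azimuthal-equidistant projection, and the
sustained-speed filter applied before any downstream analysis.

All distances are great-circle kilometres on a sphere of radius 6371.0088 km
(the WGS84 mean radius); at the few-hundred-kilometre scales of storm-petrel
foraging trips the spherical approximation is accurate to well under 0.5%.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

#: quality flags carried by every fix
QUALITY_OK = "ok"
QUALITY_REMOVED_SPEED = "removed_speed"
QUALITY_INTERPOLATED = "interpolated"

#: canonical Movebank-style column names expected in track CSVs
TRACK_CSV_COLUMNS = {
    "id": "individual-local-identifier",
    "deployment": "deployment-id",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
}


class TrackFormatError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class EmptyInputError(ValueError):
    """The input file contains no usable rows."""


class DegenerateTrackError(ValueError):
    """A track no longer satisfies the >= 2 usable fixes invariant."""


class BearingUndefinedError(ValueError):
    """Initial bearing requested between two identical points."""


class ProjectionDomainError(ValueError):
    """Point outside the domain of the colony-centred projection."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position in decimal degrees."""

    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"lon {self.lon} outside [-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")


@dataclass(frozen=True)
class Colony:
    """The breeding colony all trips start from and return to."""

    name: str
    point: GeoPoint


@dataclass(frozen=True)
class Fix:
    point: GeoPoint
    timestamp: pd.Timestamp
    quality_flag: str = QUALITY_OK


@dataclass
class Track:
    """Time-ordered GPS fixes for one logger deployment.

    ``fixes`` is a DataFrame with columns ``timestamp`` (tz-aware UTC),
    ``lon``, ``lat`` and ``quality_flag``; timestamps are strictly
    increasing and at least two fixes are present.
    """

    bird_id: str
    deployment_id: str
    sex: str = "unknown"
    season: str = "unknown"
    stage: str = "unknown"
    year: int = 0
    fixes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        df = self.fixes
        required = {"timestamp", "lon", "lat"}
        if not required.issubset(df.columns):
            raise TrackFormatError(f"track fixes need columns {sorted(required)}")
        if "quality_flag" not in df.columns:
            df = df.assign(quality_flag=QUALITY_OK)
        if len(df) < 2:
            raise DegenerateTrackError(
                f"track {self.deployment_id}: needs >= 2 fixes, got {len(df)}"
            )
        ts = df["timestamp"]
        if ts.dt.tz is None:
            raise TrackFormatError("timestamps must be timezone-aware UTC")
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(f"track {self.deployment_id}: timestamps not strictly increasing")
        self.fixes = df.reset_index(drop=True)

    def retained(self) -> pd.DataFrame:
        """Fixes not flagged as removed; the view downstream stages consume."""
        df = self.fixes
        return df[df["quality_flag"] != QUALITY_REMOVED_SPEED].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class SpeedFilterReport:
    n_total: int
    n_removed: int

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# Track I/O
# ---------------------------------------------------------------------------

def read_tracks(
    path,
    metadata: Mapping[str, Mapping] | None = None,
) -> tuple[list[Track], int]:
    """Read a Movebank-style track CSV into one :class:`Track` per deployment.

    ``metadata`` maps deployment id -> mapping with any of ``season``,
    ``stage``, ``sex``, ``year``. Rows with unparseable coordinates or
    timestamps are dropped; duplicate timestamps within a deployment keep
    the first occurrence. Returns ``(tracks, n_rows_dropped)``.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data") from None
    for col in TRACK_CSV_COLUMNS.values():
        if col not in raw.columns:
            raise TrackFormatError(f"{path}: missing required column '{col}'")
    if raw.empty:
        raise EmptyInputError(f"{path}: no rows")

    df = pd.DataFrame(
        {
            "bird_id": raw[TRACK_CSV_COLUMNS["id"]].astype(str),
            "deployment_id": raw[TRACK_CSV_COLUMNS["deployment"]].astype(str),
            "timestamp": pd.to_datetime(
                raw[TRACK_CSV_COLUMNS["timestamp"]], utc=True, errors="coerce",
                format="mixed",
            ),
            "lon": pd.to_numeric(raw[TRACK_CSV_COLUMNS["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[TRACK_CSV_COLUMNS["lat"]], errors="coerce"),
        }
    )
    ok = (
        df["timestamp"].notna()
        & df["lon"].between(-180, 180)
        & df["lat"].between(-90, 90)
    )
    n_dropped = int((~ok).sum())
    df = df[ok]

    metadata = metadata or {}
    tracks: list[Track] = []
    for dep_id, grp in df.groupby("deployment_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        grp = grp[~grp["timestamp"].duplicated(keep="first")]
        if len(grp) < 2:
            n_dropped += len(grp)
            continue
        meta = dict(metadata.get(dep_id, {}))
        tracks.append(
            Track(
                bird_id=str(grp["bird_id"].iloc[0]),
                deployment_id=str(dep_id),
                sex=str(meta.get("sex", "unknown")),
                season=str(meta.get("season", "unknown")),
                stage=str(meta.get("stage", "unknown")),
                year=int(meta.get("year", 0)),
                fixes=grp[["timestamp", "lon", "lat"]].assign(quality_flag=QUALITY_OK),
            )
        )
    return tracks, n_dropped


def write_tracks_csv(tracks: Iterable[Track], path) -> None:
    """Write tracks back out in the Movebank-style CSV layout."""
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    TRACK_CSV_COLUMNS["id"]: tr.bird_id,
                    TRACK_CSV_COLUMNS["deployment"]: tr.deployment_id,
                    TRACK_CSV_COLUMNS["timestamp"]: tr.fixes["timestamp"].dt.strftime(
                        "%Y-%m-%dT%H:%M:%SZ"
                    ),
                    TRACK_CSV_COLUMNS["lon"]: tr.fixes["lon"],
                    TRACK_CSV_COLUMNS["lat"]: tr.fixes["lat"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Geodesy
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km; accepts scalars or arrays (broadcast)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(a))


def point_distance_km(a: GeoPoint, b: GeoPoint) -> float:
    return float(haversine_km(a.lon, a.lat, b.lon, b.lat))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing in [0, 360), clockwise from true north.

    Raises :class:`BearingUndefinedError` for scalar coincident endpoints.
    """
    scalar = np.isscalar(lon1) and np.isscalar(lat1) and np.isscalar(lon2) and np.isscalar(lat2)
    if scalar and lon1 == lon2 and lat1 == lat2:
        raise BearingUndefinedError("bearing undefined between identical points")
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    return float(theta) if scalar else theta


def point_bearing_deg(a: GeoPoint, b: GeoPoint) -> float:
    return float(initial_bearing_deg(a.lon, a.lat, b.lon, b.lat))


# ---------------------------------------------------------------------------
# Colony-centred azimuthal equidistant projection
# ---------------------------------------------------------------------------

def project_aeqd(lon, lat, colony: Colony):
    """Project lon/lat to (x, y) km in an azimuthal-equidistant frame centred
    on the colony. Colony-to-point distances are preserved exactly by
    construction: sqrt(x^2 + y^2) equals the great-circle range.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    c_km = haversine_km(colony.point.lon, colony.point.lat, lon, lat)
    if np.any(c_km > EARTH_RADIUS_KM * (np.pi - 1e-6)):
        raise ProjectionDomainError("point (near-)antipodal to the colony")
    az = np.radians(
        initial_bearing_deg(
            np.broadcast_to(colony.point.lon, lon.shape) if lon.shape else colony.point.lon,
            np.broadcast_to(colony.point.lat, lat.shape) if lat.shape else colony.point.lat,
            lon,
            lat,
        )
    )
    x = c_km * np.sin(az)
    y = c_km * np.cos(az)
    # coincident with the colony: bearing is arbitrary but range is 0
    x = np.where(c_km == 0.0, 0.0, x)
    y = np.where(c_km == 0.0, 0.0, y)
    return x, y


def unproject_aeqd(x, y, colony: Colony):
    """Inverse of :func:`project_aeqd`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.hypot(x, y) / EARTH_RADIUS_KM
    az = np.arctan2(x, y)
    lat0 = np.radians(colony.point.lat)
    lon0 = np.radians(colony.point.lon)
    sin_lat = np.sin(lat0) * np.cos(c) + np.cos(lat0) * np.sin(c) * np.cos(az)
    lat = np.arcsin(np.clip(sin_lat, -1.0, 1.0))
    lon = lon0 + np.arctan2(
        np.sin(az) * np.sin(c) * np.cos(lat0), np.cos(c) - np.sin(lat0) * sin_lat
    )
    lon = (np.degrees(lon) + 180.0) % 360.0 - 180.0
    return lon, np.degrees(lat)


# ---------------------------------------------------------------------------
# Sustained-speed filter
# ---------------------------------------------------------------------------

def speed_filter(
    track: Track, vmax_km_h: float = 50.0, window_h: float = 2.0
) -> tuple[Track, SpeedFilterReport]:
    """Flag fixes requiring unrealistic sustained travel speed.

    Applied forward-iteratively against the last retained fix: a fix is
    flagged ``removed_speed`` when it cannot be reached from the previous
    retained fix at ``vmax_km_h`` within the elapsed time, with the speed
    assessed over a span of at least ``window_h`` hours (so a single
    short-interval jitter must exceed the distance coverable in the full
    sustain window before it is removed). The first fix is always retained.
    """
    df = track.fixes
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    t_h = (df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    flags = df["quality_flag"].to_numpy(dtype=object).copy()

    last = None
    for i in range(len(df)):
        if flags[i] == QUALITY_REMOVED_SPEED:
            continue
        if last is None:
            last = i
            continue
        dist = float(haversine_km(lon[last], lat[last], lon[i], lat[i]))
        dt = t_h[i] - t_h[last]
        if dist > vmax_km_h * max(dt, window_h):
            flags[i] = QUALITY_REMOVED_SPEED
        else:
            last = i

    n_removed = int(np.sum(flags == QUALITY_REMOVED_SPEED) - np.sum(df["quality_flag"] == QUALITY_REMOVED_SPEED))
    new_df = df.assign(quality_flag=flags)
    if int(np.sum(flags != QUALITY_REMOVED_SPEED)) < 2:
        raise DegenerateTrackError(
            f"track {track.deployment_id}: speed filter left < 2 fixes"
        )
    filtered = replace(track, fixes=new_df)
    return filtered, SpeedFilterReport(n_total=len(df), n_removed=n_removed)
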
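"""First passage time (FPT) and area-restricted-search classification.

FPT at a location is the time the trajectory takes to cross a circle of
radius r centred there, summing backward and forward exit times with exit
instants linearly interpolated between the straddling hourly positions.
The radius maximizing the variance of log FPT over a trip identifies that
trip's search scale; the arithmetic mean of per-trip peaks, snapped to the
radius ladder, defines the population scale. Original fixes whose FPT at
the population scale exceeds the grand mean FPT across all trips are
labelled foraging.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geotrack import Colony, project_aeqd
from .trips import Trip

LABEL_FORAGING = "foraging"
LABEL_TRAVELLING = "travelling"
LABEL_UNLABELLED = "unlabelled"


class ScaleUndefinedError(ValueError):
    """No trip yields enough defined FPT values to pick a search scale."""


def default_radius_ladder(n: int = 30, r_min: float = 2.0, r_max: float = 250.0) -> np.ndarray:
    """Log-spaced radius ladder bracketing plausible storm-petrel ARS scales."""
    return np.geomspace(r_min, r_max, n)


@dataclass
class FPTProfile:
    """Per-trip FPT surface over the radius ladder."""

    trip: Trip
    hourly: pd.DataFrame  # t_h, x_km, y_km, segment, interpolated
    radii_km: np.ndarray
    fpt_h: np.ndarray  # [n_hourly x n_radii], NaN where undefined
    varlog: np.ndarray = field(init=False)
    peak_radius_km: float | None = field(init=False)

    def __post_init__(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            logf = np.log(self.fpt_h)
            counts = np.sum(np.isfinite(logf), axis=0)
            self.varlog = np.where(
                counts >= 2, np.nanvar(logf, axis=0, ddof=1), np.nan
            )
        if np.all(~np.isfinite(self.varlog)):
            self.peak_radius_km = None
        else:
            # ties resolve to the smaller radius (first maximum)
            self.peak_radius_km = float(self.radii_km[np.nanargmax(self.varlog)])


def interpolate_hourly(trip: Trip, colony: Colony, max_gap_h: float = 6.0) -> pd.DataFrame:
    """Linearly interpolate the trip to whole-hour offsets from its start.

    Interpolation happens in colony-centred projected XY. Gaps longer than
    ``max_gap_h`` are left as breaks: hours falling inside them are
    omitted and the ``segment`` counter increments across the break.
    """
    df = trip.fixes
    ts = df["timestamp"]
    t_h = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    x, y = project_aeqd(df["lon"].to_numpy(), df["lat"].to_numpy(), colony)
    span = t_h[-1]
    if span < 1.0:
        warnings.warn(f"trip {trip.trip_id}: shorter than 1 h; no hourly positions", stacklevel=2)
        return pd.DataFrame(columns=["t_h", "x_km", "y_km", "segment", "interpolated"])

    hours = np.arange(0.0, np.floor(span) + 0.5, 1.0)
    # bracketing fix for each hour
    idx = np.searchsorted(t_h, hours, side="right")
    idx = np.clip(idx, 1, len(t_h) - 1)
    gap = t_h[idx] - t_h[idx - 1]
    exact = np.isclose(hours[:, None], t_h[None, :], atol=1e-9).any(axis=1)
    keep = exact | (gap <= max_gap_h)

    hx = np.interp(hours, t_h, x)
    hy = np.interp(hours, t_h, y)
    # segment breaks wherever an omitted hour (or an over-long bracket) separates kept hours
    big_gap_here = (~exact) & (gap > max_gap_h)
    segment = np.cumsum(big_gap_here | ~keep)[keep]
    # renumber segments consecutively
    _, segment = np.unique(segment, return_inverse=True)

    return pd.DataFrame(
        {
            "t_h": hours[keep],
            "x_km": hx[keep],
            "y_km": hy[keep],
            "segment": segment,
            "interpolated": ~exact[keep],
        }
    )


def compute_fpt(hourly: pd.DataFrame, radii_km, trip: Trip | None = None) -> FPTProfile:
    """FPT at every hourly position for every ladder radius.

    For position p and radius r the backward and forward exit instants are
    found by scanning hourly positions within the same segment and
    linearly interpolating the crossing between the straddling positions;
    FPT is their sum and is missing (NaN) where either side never exits
    within the trip.
    """
    radii = np.asarray(radii_km, dtype=float)
    if radii.ndim != 1 or len(radii) < 2 or np.any(np.diff(radii) <= 0):
        raise ValueError("radius ladder must be strictly increasing")
    n = len(hourly)
    fpt = np.full((n, len(radii)), np.nan)
    if n >= 3:
        xy = hourly[["x_km", "y_km"]].to_numpy()
        seg = hourly["segment"].to_numpy()
        def _exit_times(d: np.ndarray) -> np.ndarray:
            """Hours from the centre to the first crossing of each radius,
            given distances ``d`` to the consecutive hourly positions ahead
            (NaN where never crossed)."""
            out = np.full(len(radii), np.nan)
            if d.size == 0:
                return out
            cmax = np.maximum.accumulate(d)
            j = np.searchsorted(cmax, radii, side="left")
            valid = j < d.size
            jv = j[valid]
            d_prev = np.where(jv > 0, d[np.maximum(jv - 1, 0)], 0.0)
            d_next = d[jv]
            frac = np.where(d_next > d_prev, (radii[valid] - d_prev) / (d_next - d_prev), 1.0)
            out[valid] = jv + frac
            return out

        for s in np.unique(seg):
            m = seg == s
            pts = xy[m]
            k = len(pts)
            if k < 3:
                continue
            D = cdist(pts, pts)
            rows = np.flatnonzero(m)
            for i in range(k):
                fwd = _exit_times(D[i, i + 1 :])
                bwd = _exit_times(D[i, :i][::-1])
                fpt[rows[i]] = fwd + bwd
    return FPTProfile(trip=trip, hourly=hourly, radii_km=radii, fpt_h=fpt)


def fpt_profile(trip: Trip, colony: Colony, radii_km=None, max_gap_h: float = 6.0) -> FPTProfile:
    """Convenience wrapper: interpolate a trip hourly and compute its FPT."""
    if radii_km is None:
        radii_km = default_radius_ladder()
    hourly = interpolate_hourly(trip, colony, max_gap_h=max_gap_h)
    return compute_fpt(hourly, radii_km, trip=trip)


def select_search_scale(profiles: list[FPTProfile]) -> float:
    """Population search scale: mean of per-trip var(log FPT) peak radii,
    snapped to the nearest ladder radius (ties to the smaller)."""
    peaks = [p.peak_radius_km for p in profiles if p.peak_radius_km is not None]
    if not peaks:
        raise ScaleUndefinedError("no trip has a defined var(log FPT) peak")
    ladder = profiles[0].radii_km
    mean_peak = float(np.mean(peaks))
    return float(ladder[np.argmin(np.abs(ladder - mean_peak))])


def classify_foraging(
    profiles: list[FPTProfile], population_scale_km: float
) -> tuple[pd.DataFrame, pd.Series]:
    """Label original fixes foraging/travelling at the population scale.

    Each original fix takes the FPT of its nearest-in-time hourly
    position; fixes with undefined FPT stay unlabelled and are excluded
    from the per-trip proportion of time foraging. The foraging threshold
    is the grand mean FPT across all labelled locations of all trips
    (label foraging iff FPT / grand mean > 1).
    """
    per_fix = []
    for p in profiles:
        if p.trip is None:
            raise ValueError("profile lacks its trip reference")
        ridx = int(np.argmin(np.abs(p.radii_km - population_scale_km)))
        ts = p.trip.fixes["timestamp"]
        t_h = (ts - ts.iloc[0]).dt.total_seconds().to_numpy() / 3600.0
        if len(p.hourly):
            hourly_t = p.hourly["t_h"].to_numpy()
            nearest = np.argmin(np.abs(t_h[:, None] - hourly_t[None, :]), axis=1)
            vals = p.fpt_h[nearest, ridx]
        else:
            vals = np.full(len(t_h), np.nan)
        per_fix.append(
            pd.DataFrame(
                {
                    "trip_id": p.trip.trip_id,
                    "timestamp": ts.to_numpy(),
                    "lon": p.trip.fixes["lon"].to_numpy(),
                    "lat": p.trip.fixes["lat"].to_numpy(),
                    "season": p.trip.season,
                    "year": p.trip.year,
                    "fpt_at_scale_h": vals,
                }
            )
        )
    table = pd.concat(per_fix, ignore_index=True)
    defined = table["fpt_at_scale_h"].notna()
    grand_mean = table.loc[defined, "fpt_at_scale_h"].mean()
    label = np.where(
        ~defined,
        LABEL_UNLABELLED,
        np.where(table["fpt_at_scale_h"] > grand_mean, LABEL_FORAGING, LABEL_TRAVELLING),
    )
    table["label"] = label
    labelled = table[table["label"] != LABEL_UNLABELLED]
    prop = labelled.groupby("trip_id", sort=True)["label"].apply(
        lambda s: float((s == LABEL_FORAGING).mean())
    )
    prop.name = "proportion_foraging"
    return table, prop
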
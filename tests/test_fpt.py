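"""First passage time: hourly interpolation, the FPT geometry, search-scale
selection and foraging classification."""
import numpy as np
import pandas as pd
import pytest

from petreltrack import fpt as fm
from petreltrack import synthetic as syn
from petreltrack.trips import Trip

from conftest import make_track


def hourly_frame(x, y):
    n = len(x)
    return pd.DataFrame(
        {"t_h": np.arange(n, dtype=float), "x_km": np.asarray(x, float),
         "y_km": np.asarray(y, float), "segment": 0, "interpolated": False}
    )


def trip_from_track(track):
    df = track.retained().copy()
    df["dist_km"] = 0.0
    return Trip(
        deployment_id=track.deployment_id, bird_id=track.bird_id, sex=track.sex,
        season=track.season, stage=track.stage, year=track.year, fixes=df,
        complete=True, trip_id="t0",
    )


# ---------------------------------------------------------------------------
# Hourly interpolation
# ---------------------------------------------------------------------------

def test_interpolate_midpoint(colony):
    lat0 = colony.point.lat
    tr = make_track([colony.point.lon] * 2, [lat0, lat0 + 0.2], dt_h=2.0)
    h = fm.interpolate_hourly(trip_from_track(tr), colony)
    assert len(h) == 3
    mid = h.iloc[1]
    assert mid["interpolated"]
    assert mid["y_km"] == pytest.approx(0.5 * h.iloc[2]["y_km"], abs=1e-9)


def test_interpolate_hourly_track_unchanged(colony):
    lat0 = colony.point.lat
    lats = lat0 + np.linspace(0, 0.5, 6)
    tr = make_track([colony.point.lon] * 6, lats, dt_h=1.0)
    h = fm.interpolate_hourly(trip_from_track(tr), colony)
    assert len(h) == 6
    assert not h["interpolated"].any()
    from petreltrack.geotrack import project_aeqd
    x, y = project_aeqd(tr.fixes["lon"].to_numpy(), tr.fixes["lat"].to_numpy(), colony)
    assert np.max(np.abs(h["y_km"].to_numpy() - y)) < 1e-9


def test_interpolate_gap_left_as_break(colony):
    lat0 = colony.point.lat
    ts = pd.to_datetime(
        ["2018-01-01T00:00Z", "2018-01-01T02:00Z", "2018-01-01T14:00Z", "2018-01-01T16:00Z"]
    )
    fixes = pd.DataFrame(
        {"timestamp": ts, "lon": [colony.point.lon] * 4,
         "lat": [lat0, lat0 + 0.1, lat0 + 1.0, lat0 + 1.1]}
    )
    tr = make_track([0.0] * 2, [0.0, 0.1])  # placeholder for metadata
    trip = Trip(deployment_id="d", bird_id="b", sex="F", season="hot",
                stage="incubation", year=2018,
                fixes=fixes.assign(dist_km=0.0), complete=True, trip_id="t")
    h = fm.interpolate_hourly(trip, colony)
    # no interpolated hours inside the 12-h gap; two segments
    inside = h[(h["t_h"] > 2) & (h["t_h"] < 14)]
    assert len(inside) == 0
    assert h["segment"].nunique() == 2


def test_short_trip_warns_and_returns_empty(colony):
    ts = pd.to_datetime(["2018-01-01T00:00Z", "2018-01-01T00:30Z"])
    fixes = pd.DataFrame({"timestamp": ts, "lon": [0.0, 0.1], "lat": [0.0, 0.0],
                          "dist_km": 0.0})
    trip = Trip("d", "b", "F", "hot", "incubation", 2018, fixes, True, trip_id="t")
    with pytest.warns(UserWarning):
        h = fm.interpolate_hourly(trip, colony)
    assert len(h) == 0


# ---------------------------------------------------------------------------
# FPT geometry
# ---------------------------------------------------------------------------

def test_fpt_straight_line_matches_2r_over_v():
    v = 10.0  # km/h, hourly positions
    h = hourly_frame(np.arange(41) * v, np.zeros(41))
    radii = np.array([20.0, 50.0, 100.0])
    prof = fm.compute_fpt(h, radii)
    i = 20  # interior point
    for j, r in enumerate(radii):
        assert prof.fpt_h[i, j] == pytest.approx(2 * r / v, rel=0.02)


def test_fpt_slow_dwell_bounds_below(colony):
    # enter, sit nearly still for 5 h inside r, leave: FPT >= dwell length
    x = np.concatenate([np.arange(-50, 0, 10), np.zeros(5), np.arange(10, 60, 10)])
    y = np.concatenate([np.zeros(5), np.linspace(0, 0.5, 5), np.full(5, 0.5)])
    prof = fm.compute_fpt(hourly_frame(x, y), np.array([5.0, 20.0]))
    mid = 7
    assert prof.fpt_h[mid, 1] >= 5.0


def test_fpt_reversal_symmetry():
    rng = np.random.default_rng(5)
    steps = rng.normal(0, 4, size=(40, 2))
    xy = np.cumsum(steps, axis=0)
    fwd = fm.compute_fpt(hourly_frame(xy[:, 0], xy[:, 1]), np.array([5.0, 10.0, 25.0]))
    rev = fm.compute_fpt(hourly_frame(xy[::-1, 0], xy[::-1, 1]), np.array([5.0, 10.0, 25.0]))
    assert np.allclose(fwd.fpt_h, rev.fpt_h[::-1], equal_nan=True, atol=1e-9)


def test_fpt_monotone_in_radius_and_translation_invariant():
    rng = np.random.default_rng(11)
    xy = np.cumsum(rng.normal(0, 5, size=(60, 2)), axis=0)
    ladder = fm.default_radius_ladder()
    prof = fm.compute_fpt(hourly_frame(xy[:, 0], xy[:, 1]), ladder)
    f = prof.fpt_h
    for i in range(f.shape[0]):
        row = f[i][~np.isnan(f[i])]
        assert np.all(np.diff(row) >= -1e-9)
    shifted = hourly_frame(xy[:, 0], xy[:, 1])
    shifted["t_h"] += 137.0
    prof2 = fm.compute_fpt(shifted, ladder)
    assert np.allclose(prof.fpt_h, prof2.fpt_h, equal_nan=True)


def test_fpt_oversized_radii_give_missing_columns():
    h = hourly_frame(np.arange(10) * 5.0, np.zeros(10))
    prof = fm.compute_fpt(h, np.array([10.0, 1000.0]))
    assert np.isnan(prof.fpt_h[:, 1]).all()


# ---------------------------------------------------------------------------
# Search-scale selection and classification
# ---------------------------------------------------------------------------

def fake_profile(radii, fpt_matrix, trip=None):
    return fm.FPTProfile(
        trip=trip,
        hourly=hourly_frame(np.zeros(fpt_matrix.shape[0]), np.zeros(fpt_matrix.shape[0])),
        radii_km=np.asarray(radii, float),
        fpt_h=np.asarray(fpt_matrix, float),
    )


def test_select_scale_unanimous_and_single():
    radii = [10, 20, 30, 40, 50]
    # variance of log FPT maximal in the 30-km column
    col = lambda spread: np.exp(np.linspace(-spread, spread, 6))
    mat = np.column_stack([col(0.1), col(0.2), col(2.0), col(0.3), col(0.1)])
    p1, p2 = fake_profile(radii, mat), fake_profile(radii, mat * 2)
    assert p1.peak_radius_km == 30
    assert fm.select_search_scale([p1, p2]) == 30
    assert fm.select_search_scale([p1]) == 30


def test_select_scale_tie_takes_smaller_radius():
    radii = [10, 20, 30]
    col = np.exp(np.linspace(-1, 1, 5))
    mat = np.column_stack([col, col, np.exp(np.linspace(-0.1, 0.1, 5))])
    assert fake_profile(radii, mat).peak_radius_km == 10


def test_select_scale_undefined():
    p = fake_profile([10, 20], np.full((4, 2), np.nan))
    with pytest.raises(fm.ScaleUndefinedError):
        fm.select_search_scale([p])


def test_classify_foraging_strict_threshold(colony):
    lat0 = colony.point.lat
    tr = make_track([colony.point.lon] * 4, [lat0, lat0 + 0.1, lat0 + 0.2, lat0 + 0.3],
                    dt_h=1.0)
    trip = trip_from_track(tr)
    radii = [10.0, 20.0]
    mat = np.array([[np.nan, 2.0], [np.nan, 0.5], [np.nan, 0.5], [np.nan, 1.0]])
    prof = fake_profile(radii, mat, trip=trip)
    table, prop = fm.classify_foraging([prof], population_scale_km=20.0)
    # grand mean 1.0: only the strict > survives
    assert prop.iloc[0] == pytest.approx(0.25)
    assert (table["label"] == "foraging").sum() == 1


def test_classify_foraging_all_equal_gives_zero(colony):
    lat0 = colony.point.lat
    tr = make_track([colony.point.lon] * 4, [lat0 + 0.1 * i for i in range(4)], dt_h=1.0)
    trip = trip_from_track(tr)
    mat = np.full((4, 1), 3.3)
    prof = fake_profile([15.0], mat, trip=trip)
    table, prop = fm.classify_foraging([prof], 15.0)
    assert prop.iloc[0] == 0.0
    assert set(table["label"]) == {"travelling"}


def test_classify_foraging_undefined_fpt_unlabelled(colony):
    lat0 = colony.point.lat
    tr = make_track([colony.point.lon] * 3, [lat0, lat0 + 0.1, lat0 + 0.2], dt_h=1.0)
    trip = trip_from_track(tr)
    mat = np.array([[np.nan], [1.0], [5.0]])
    prof = fake_profile([15.0], mat, trip=trip)
    table, prop = fm.classify_foraging([prof], 15.0)
    assert (table["label"] == "unlabelled").sum() == 1
    assert prop.iloc[0] == pytest.approx(0.5)  # one of two labelled is foraging


def test_scale_recovery_single_replicates():
    ladder = fm.default_radius_ladder()
    for R in (20.0, 40.0):
        rng = np.random.default_rng(123)
        profs = [
            fm.compute_fpt(syn.simulate_ars_trajectory(R, seed=rng), ladder)
            for _ in range(3)
        ]
        s = fm.select_search_scale(profs)
        assert R / 2 <= s <= 2 * R
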
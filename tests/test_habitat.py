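"""Environmental annotation, the opposite-season availability design and
the selection models."""
import numpy as np
import pandas as pd
import pytest
import xarray as xr

from petreltrack import habitat as hab


def toy_env(days=3, lat0=-20.0, lon0=-10.0, n=21, step=0.5, sst_fn=None):
    """Small layer set; SST from sst_fn(lon, lat, day_index), others constant."""
    lats = lat0 + np.arange(n) * step
    lons = lon0 + np.arange(n) * step
    times = pd.date_range("2018-06-01", periods=days, freq="D")
    shape = (days, n, n)
    LON, LAT = np.meshgrid(lons, lats)
    if sst_fn is None:
        sst = np.full(shape, 20.0)
    else:
        sst = np.stack([sst_fn(LON, LAT, t) for t in range(days)])
    const = lambda v: np.full(shape, float(v))
    ds = xr.Dataset(
        {
            "air_temp_c": (("time", "lat", "lon"), const(21)),
            "cloud_cover": (("time", "lat", "lon"), const(0.5)),
            "rain_mm": (("time", "lat", "lon"), const(0.1)),
            "wind_u_ms": (("time", "lat", "lon"), const(5)),
            "wind_v_ms": (("time", "lat", "lon"), const(-5)),
            "chl_mg_m3": (("time", "lat", "lon"), const(0.1)),
            "sst_c": (("time", "lat", "lon"), sst),
            "wave_dir_deg": (("time", "lat", "lon"), const(160)),
            "wave_height_m": (("time", "lat", "lon"), const(2.2)),
        },
        coords={"time": times, "lat": lats, "lon": lons},
    )
    return hab.EnvLayerSet(ds)


def locs(lons, lats, stamps):
    return pd.DataFrame(
        {"timestamp": pd.to_datetime(stamps, utc=True), "lon": lons, "lat": lats}
    )


# ---------------------------------------------------------------------------
# Wind convention
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "u,v,speed,direction",
    [
        (0.0, -5.0, 5.0, 0.0),    # northerly: blows toward the south, FROM north
        (-3.0, 0.0, 3.0, 90.0),   # easterly
        (3.0, 4.0, 5.0, None),    # 3-4-5 speed check
    ],
)
def test_wind_from_uv(u, v, speed, direction):
    s, d = hab.wind_from_uv(u, v)
    assert float(s) == pytest.approx(speed)
    if direction is not None:
        assert float(d) == pytest.approx(direction)


def test_wind_calm_direction_undefined():
    s, d = hab.wind_from_uv(0.0, 0.0)
    assert float(s) == 0.0 and np.isnan(d)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def test_annotate_cell_center_exact_and_per_day():
    env = toy_env(days=3, sst_fn=lambda LON, LAT, t: np.full(LON.shape, 20.0 + t))
    pts = locs([-9.5, -9.5], [-19.5, -19.5],
               ["2018-06-01T10:00", "2018-06-03T04:00"])
    ann, dropped = hab.annotate(pts, env)
    assert dropped == 0
    assert list(ann["sst_c"]) == [20.0, 22.0]
    assert ann["wind_speed_ms"].iloc[0] == pytest.approx(np.sqrt(50))
    assert ann["wind_dir_deg"].iloc[0] == pytest.approx(315.0)


def test_annotate_linear_gradient_error_below_half_cell():
    slope = 0.8  # degC per degree longitude
    env = toy_env(sst_fn=lambda LON, LAT, t: 20.0 + slope * (LON + 10.0))
    rng = np.random.default_rng(0)
    lons = rng.uniform(-9.8, -1.2, 40)
    lats = rng.uniform(-19.8, -11.2, 40)
    pts = locs(lons, lats, ["2018-06-02T12:00"] * 40)
    ann, _ = hab.annotate(pts, env)
    expected = 20.0 + slope * (lons + 10.0)
    assert np.max(np.abs(ann["sst_c"] - expected)) <= slope * 0.5 * 0.5 + 1e-9


def test_annotate_date_outside_coverage():
    env = toy_env(days=2)
    pts = locs([-9.0], [-19.0], ["2018-07-01T00:00"])
    with pytest.raises(hab.LayerCoverageError):
        hab.annotate(pts, env)


# ---------------------------------------------------------------------------
# Used/available design
# ---------------------------------------------------------------------------

def test_build_used_available_contract():
    env = toy_env(days=3)
    focal = locs([-9.0, -8.5, -8.0], [-19.0, -18.5, -18.0],
                 ["2018-06-01T05:00", "2018-06-02T07:00", "2018-06-03T09:00"])
    other = locs([-5.0, -5.5], [-15.0, -15.5],
                 ["2018-06-10T00:00", "2018-06-11T00:00"])
    uv, dropped = hab.build_used_available(focal, other, env, seed=7)
    avail = uv[uv["role"] == "available"]
    assert len(avail) == len(other)  # one re-timed copy per opposite location
    # availability never invents coordinates
    assert set(zip(avail["lon"], avail["lat"])) <= set(zip(other["lon"], other["lat"]))
    # timestamps drawn from the focal season's empirical distribution
    assert set(avail["timestamp"]) <= set(pd.to_datetime(focal["timestamp"], utc=True))
    uv2, _ = hab.build_used_available(focal, other, env, seed=7)
    pd.testing.assert_frame_equal(uv, uv2)


def test_build_used_available_empty_input():
    env = toy_env()
    pts = locs([-9.0], [-19.0], ["2018-06-01T00:00"])
    with pytest.raises(hab.DesignError):
        hab.build_used_available(pts.iloc[:0], pts, env)


# ---------------------------------------------------------------------------
# Selection models
# ---------------------------------------------------------------------------

def synth_table(n, seed, informative="sst_c", margin=3.0, constant=None):
    """Two classes separated by one variable with a wide margin; the other
    variables are exchangeable noise."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({v: rng.normal(0, 1, n) for v in hab.ENV_VARIABLES})
    y = np.repeat(["used", "available"], n // 2)
    df[informative] = np.where(y == "used", -margin, margin) + rng.normal(0, 0.3, n)
    if constant is not None:
        df[constant] = 1.0
    df["role"] = y
    return df


def test_selection_model_separable_data():
    df = synth_table(300, seed=0)
    res = hab.fit_selection_model(df, "role", seed=1, n_trees=200)
    assert all(a >= 0.99 for a in res.oob_class_accuracy.values())


def test_selection_model_permuted_labels_chance_level():
    rng = np.random.default_rng(1)
    df = synth_table(600, seed=2)
    df["role"] = rng.permutation(df["role"].to_numpy())
    res = hab.fit_selection_model(df, "role", seed=3, n_trees=200)
    overall = np.mean(list(res.oob_class_accuracy.values()))
    assert overall == pytest.approx(0.5, abs=0.07)


def test_selection_model_stable_under_duplication():
    df = synth_table(200, seed=4)
    res1 = hab.fit_selection_model(df, "role", seed=5, n_trees=200)
    res2 = hab.fit_selection_model(
        pd.concat([df, df], ignore_index=True), "role", seed=5, n_trees=200
    )
    for c in res1.oob_class_accuracy:
        assert res1.oob_class_accuracy[c] == pytest.approx(
            res2.oob_class_accuracy[c], abs=0.02
        )


def test_selection_model_single_class_error():
    df = synth_table(100, seed=6)
    df["role"] = "used"
    with pytest.raises(hab.DesignError):
        hab.fit_selection_model(df, "role", seed=0)


def test_permutation_importance_single_signal_and_constant():
    df = synth_table(400, seed=7, constant="rain_mm")
    res = hab.fit_selection_model(df, "role", seed=8, n_trees=200)
    imp = hab.permutation_importances(res, df, "role", seed=9)
    assert imp["sst_c"] == 100.0
    assert imp.max() == 100.0
    others = imp.drop(["sst_c"])
    assert (others <= 20.0).all()
    assert imp["rain_mm"] == 0.0


def test_partial_dependence_flat_for_ignored_variable():
    df = synth_table(300, seed=10)
    res = hab.fit_selection_model(df, "role", seed=11, n_trees=200)
    curve = hab.partial_dependence(res, df, "cloud_cover", "used")
    assert curve["median"].max() - curve["median"].min() < 0.05


def test_partial_dependence_monotone_for_driving_variable():
    df = synth_table(300, seed=12)
    res = hab.fit_selection_model(df, "role", seed=13, n_trees=200)
    curve = hab.partial_dependence(res, df, "sst_c", "used")
    n = len(curve)
    mid = curve["median"].iloc[int(0.1 * n): int(0.9 * n)].to_numpy()
    assert np.all(np.diff(mid) <= 1e-9)  # used prefers low values here


def test_partial_dependence_unknown_variable():
    df = synth_table(100, seed=14)
    res = hab.fit_selection_model(df, "role", seed=15, n_trees=50)
    with pytest.raises(KeyError):
        hab.partial_dependence(res, df, "salinity", "used")


def test_self_transfer_matches_oob_accuracy():
    df = synth_table(400, seed=16, margin=1.0)
    res = hab.fit_selection_model(df, "role", seed=17, n_trees=300)
    self_acc = hab.cross_season_transfer(res, df, "role")
    for c, a in res.oob_class_accuracy.items():
        assert self_acc[c] == pytest.approx(a, abs=0.05)


def test_transfer_schema_mismatch():
    df = synth_table(100, seed=18)
    res = hab.fit_selection_model(df, "role", seed=19, n_trees=50)
    other = df.copy()
    other["role"] = np.where(other["role"] == "used", "foo", "bar")
    with pytest.raises(hab.DesignError):
        hab.cross_season_transfer(res, other, "role")


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

def test_group_summary_identical_groups_and_constant_variable():
    rng = np.random.default_rng(20)
    df = pd.DataFrame({v: rng.normal(0, 1, 60) for v in hab.ENV_VARIABLES})
    df["rain_mm"] = 0.2
    half = pd.concat([df, df], ignore_index=True)
    half["role"] = np.repeat(["used", "available"], 60)
    out = hab.group_summary_table(half, "role", "available", "used", B=1000, seed=0)
    sst = out[out.variable == "sst_c"].iloc[0]
    assert sst["mean_difference"] == pytest.approx(0.0, abs=1e-12)
    assert sst["lcl"] <= 0.0 <= sst["ucl"]
    rain = out[out.variable == "rain_mm"].iloc[0]
    assert rain["sd_used"] == pytest.approx(0.0, abs=1e-12)
    assert rain["lcl"] == pytest.approx(0.0, abs=1e-12)
    assert rain["ucl"] == pytest.approx(0.0, abs=1e-12)
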
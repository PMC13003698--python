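"""Environmental annotation and used-vs-available habitat selection.

Nine daily environmental variables (air temperature, cloud cover, rain,
wind direction and speed, chlorophyll a, sea surface temperature, wave
direction and height) are sampled at track locations from gridded daily
layers. Within each season, availability is defined by the foraging
locations of the opposite season re-timed into the focal season's
temporal distribution: those places were demonstrably reachable but went
unused. Selection is modelled with a random-forest classifier; model
skill is summarised by out-of-bag per-class accuracy, permutation
importance scaled to 100, partial-dependence curves and cross-season
transfer accuracy.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from . import seastats

#: the nine model predictors, in reporting order
ENV_VARIABLES = [
    "air_temp_c",
    "cloud_cover",
    "rain_mm",
    "wind_dir_deg",
    "wind_speed_ms",
    "chl_mg_m3",
    "sst_c",
    "wave_dir_deg",
    "wave_height_m",
]

#: variables stored in the raster layers (wind kept as u/v components;
#: speed and direction are derived at annotation time)
RASTER_VARIABLES = [
    "air_temp_c",
    "cloud_cover",
    "rain_mm",
    "wind_u_ms",
    "wind_v_ms",
    "chl_mg_m3",
    "sst_c",
    "wave_dir_deg",
    "wave_height_m",
]


class LayerCoverageError(ValueError):
    pass


class DesignError(ValueError):
    pass


@dataclass
class EnvLayerSet:
    """Daily raster time series (CF-style dims time/lat/lon) of the nine
    variables, wind held as zonal/meridional components."""

    data: xr.Dataset

    def __post_init__(self) -> None:
        missing = set(RASTER_VARIABLES) - set(self.data.data_vars)
        if missing:
            raise ValueError(f"environmental layers missing {sorted(missing)}")
        for dim in ("time", "lat", "lon"):
            if dim not in self.data.dims:
                raise ValueError(f"layers need dimension '{dim}'")

    @property
    def dates(self) -> np.ndarray:
        return self.data["time"].dt.floor("D").to_numpy()

    def to_netcdf(self, path) -> None:
        ds = self.data
        ds = ds.assign({v: ds[v].astype("float32") for v in ds.data_vars})
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "EnvLayerSet":
        return cls(xr.open_dataset(path, engine="scipy").load())


def wind_from_uv(u, v):
    """Wind speed (m/s) and meteorological direction (degrees FROM which
    the wind blows, clockwise from north) from zonal/meridional components.
    Direction is NaN (undefined) for calm air."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    with np.errstate(invalid="ignore"):
        direction = (270.0 - np.degrees(np.arctan2(v, u))) % 360.0
    direction = np.where(speed == 0.0, np.nan, direction)
    return speed, direction


def annotate(locations: pd.DataFrame, env: EnvLayerSet) -> tuple[pd.DataFrame, int]:
    """Sample the nine variables at each location from the same-calendar-day
    layer, nearest grid cell. Returns (annotated copy, rows dropped for
    missing values). Raises :class:`LayerCoverageError` when a location's
    date is not covered.
    """
    loc = locations.reset_index(drop=True)
    days = pd.to_datetime(loc["timestamp"], utc=True).dt.floor("D").dt.tz_localize(None)
    layer_days = pd.DatetimeIndex(env.dates)
    missing_days = ~days.isin(layer_days)
    if missing_days.any():
        raise LayerCoverageError(
            f"{int(missing_days.sum())} locations dated outside the layer range "
            f"(first: {days[missing_days].iloc[0].date()})"
        )
    pts = xr.Dataset(
        {
            "time": ("points", days.to_numpy()),
            "lat": ("points", loc["lat"].to_numpy(dtype=float)),
            "lon": ("points", loc["lon"].to_numpy(dtype=float)),
        }
    )
    sampled = env.data.sel(
        time=pts["time"],
        lat=pts["lat"],
        lon=pts["lon"],
        method="nearest",
    )
    out = loc.copy()
    for v in RASTER_VARIABLES:
        out[v] = sampled[v].to_numpy()
    speed, direction = wind_from_uv(out.pop("wind_u_ms"), out.pop("wind_v_ms"))
    out["wind_speed_ms"] = speed
    out["wind_dir_deg"] = direction
    before = len(out)
    out = out.dropna(subset=ENV_VARIABLES).reset_index(drop=True)
    return out[list(loc.columns) + ENV_VARIABLES], before - len(out)


def build_used_available(
    focal_used: pd.DataFrame,
    other_used: pd.DataFrame,
    env_focal: EnvLayerSet,
    seed=None,
) -> tuple[pd.DataFrame, int]:
    """Used/available design for one season.

    Available points take the opposite season's foraging coordinates and
    timestamps resampled with replacement from the focal season's foraging
    timestamps (one re-timed copy per opposite-season location); both
    roles are annotated against the focal season's layers. Returns the
    stacked annotated table with a ``role`` column and the dropped-row
    count.
    """
    if len(focal_used) == 0 or len(other_used) == 0:
        raise DesignError("both seasons need >= 1 foraging location")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ts = pd.to_datetime(focal_used["timestamp"], utc=True).to_numpy()
    avail = pd.DataFrame(
        {
            "timestamp": ts[rng.integers(0, len(ts), size=len(other_used))],
            "lon": other_used["lon"].to_numpy(),
            "lat": other_used["lat"].to_numpy(),
        }
    )
    used = focal_used[["timestamp", "lon", "lat"]].copy()
    used_ann, d1 = annotate(used, env_focal)
    avail_ann, d2 = annotate(avail, env_focal)
    used_ann["role"] = "used"
    avail_ann["role"] = "available"
    return pd.concat([used_ann, avail_ann], ignore_index=True), d1 + d2


@dataclass
class SelectionModelResult:
    model: RandomForestClassifier
    classes: list
    oob_class_accuracy: dict
    variables: list


def fit_selection_model(
    data: pd.DataFrame,
    label_column: str,
    seed=None,
    n_trees: int = 500,
) -> SelectionModelResult:
    """Random-forest classifier over the nine predictors.

    Internal cross-validation is realised as out-of-bag prediction: each
    row is scored only by trees that did not see it, and accuracy is
    reported per class.
    """
    y = data[label_column].to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise DesignError("need >= 2 classes to fit a selection model")
    X = data[ENV_VARIABLES].to_numpy(dtype=float)
    rs = int(np.random.default_rng(seed).integers(0, 2**31 - 1)) if not isinstance(seed, int) else seed
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=rs, n_jobs=1
    )
    rf.fit(X, y)
    oob_pred = rf.classes_[np.argmax(rf.oob_decision_function_, axis=1)]
    acc = {c: float(np.mean(oob_pred[y == c] == c)) for c in classes}
    return SelectionModelResult(
        model=rf, classes=list(rf.classes_), oob_class_accuracy=acc,
        variables=list(ENV_VARIABLES),
    )


def permutation_importances(
    result: SelectionModelResult,
    data: pd.DataFrame,
    label_column: str,
    seed=None,
    n_repeats: int = 10,
) -> pd.Series:
    """Mean accuracy drop over seeded permutations of each predictor,
    rescaled so the largest drop is exactly 100."""
    X = data[result.variables].to_numpy(dtype=float)
    y = data[label_column].to_numpy()
    rs = int(np.random.default_rng(seed).integers(0, 2**31 - 1)) if not isinstance(seed, int) else seed
    imp = _sk_permutation_importance(
        result.model, X, y, n_repeats=n_repeats, random_state=rs,
        scoring="accuracy", n_jobs=1,
    )
    raw = imp.importances_mean
    top = raw.max()
    scaled = raw * (100.0 / top) if top > 0 else np.zeros_like(raw)
    return pd.Series(scaled, index=result.variables, name="importance_pct")


def partial_dependence(
    result: SelectionModelResult,
    data: pd.DataFrame,
    variable: str,
    positive_class,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Median predicted probability of ``positive_class`` (with 2.5/97.5%
    quantile band over the variation of all other variables) as
    ``variable`` sweeps a 50-point grid over its observed range."""
    if variable not in result.variables:
        raise KeyError(f"'{variable}' is not a model predictor")
    X = data[result.variables].to_numpy(dtype=float)
    j = result.variables.index(variable)
    ci = result.classes.index(positive_class)
    grid = np.linspace(X[:, j].min(), X[:, j].max(), n_grid)
    med = np.empty(n_grid)
    lo = np.empty(n_grid)
    hi = np.empty(n_grid)
    Xg = X.copy()
    for k, g in enumerate(grid):
        Xg[:, j] = g
        p = result.model.predict_proba(Xg)[:, ci]
        med[k] = np.median(p)
        lo[k], hi[k] = np.percentile(p, [2.5, 97.5])
    return pd.DataFrame({variable: grid, "median": med, "q025": lo, "q975": hi})


def cross_season_transfer(
    result: SelectionModelResult, data_other: pd.DataFrame, label_column: str
) -> dict:
    """Per-class fraction of the other season's rows predicted correctly
    by a model trained on the focal season."""
    X = data_other[result.variables].to_numpy(dtype=float)
    y = data_other[label_column].to_numpy()
    if set(pd.unique(y)) - set(result.classes):
        raise DesignError("class labels differ between the model and the transfer set")
    pred = result.model.predict(X)
    return {c: float(np.mean(pred[y == c] == c)) for c in sorted(pd.unique(y))}


def group_summary_table(
    data: pd.DataFrame,
    group_column: str,
    group_a,
    group_b,
    B: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Per-variable mean +- SD by group and the bootstrap mean difference
    (group_b minus group_a) with its percentile 95% CI."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = data[data[group_column] == group_a]
    b = data[data[group_column] == group_b]
    rows = []
    for v in ENV_VARIABLES:
        xa = a[v].to_numpy(dtype=float)
        xb = b[v].to_numpy(dtype=float)
        diff, lcl, ucl = seastats.bootstrap_mean_diff(xa, xb, B=B, seed=rng)
        rows.append(
            {
                "variable": v,
                f"mean_{group_a}": xa.mean(),
                f"sd_{group_a}": xa.std(ddof=1) if len(xa) > 1 else 0.0,
                f"mean_{group_b}": xb.mean(),
                f"sd_{group_b}": xb.std(ddof=1) if len(xb) > 1 else 0.0,
                "mean_difference": diff,
                "lcl": lcl,
                "ucl": ucl,
            }
        )
    return pd.DataFrame(rows)
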
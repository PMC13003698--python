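"""End-to-end orchestration: speed filter -> trip segmentation -> FPT
foraging classification -> kernel UDs and overlap -> seasonal statistics
-> used-vs-available habitat selection, driven by one config and one
master seed (per-stage seeds are derived deterministically from it).
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fpt as fpt_mod
from . import habitat as hab
from . import seastats
from . import spaceuse
from . import synthetic
from . import trips as trips_mod
from .geotrack import Colony, GeoPoint, read_tracks, speed_filter
from .habitat import EnvLayerSet

__version__ = "0.1.0"

log = logging.getLogger("petreltrack")

STAGES = ["load", "filter", "trips", "fpt", "ud", "overlap", "stats", "habitat"]


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All paths, thresholds and the master seed for one analysis run."""

    out_dir: str = "petreltrack_out"
    simulate: bool = True          # generate the synthetic bundle in memory
    tracks_path: str | None = None
    attendance_path: str | None = None
    env_paths: dict = field(default_factory=dict)   # season -> NetCDF path
    deployments: dict = field(default_factory=dict)  # deployment -> metadata
    colony_name: str = synthetic.EGG_ISLAND.name
    colony_lon: float = synthetic.EGG_ISLAND.point.lon
    colony_lat: float = synthetic.EGG_ISLAND.point.lat
    vmax_km_h: float = 50.0
    speed_window_h: float = 2.0
    inner_buff_km: float = 20.0
    return_buff_km: float = 30.0
    min_locs: int = 6
    bandwidth_km: float | None = 44.0  # None -> ad hoc href per point set
    cell_km: float = 1.0
    ud_levels: tuple = (50, 75, 95)
    fpt_r_min_km: float = 2.0
    fpt_r_max_km: float = 250.0
    fpt_n_radii: int = 30
    max_gap_h: float = 6.0
    bootstrap_B: int = 10_000
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vmax_km_h", "speed_window_h", "inner_buff_km", "return_buff_km",
                     "min_locs", "cell_km", "bootstrap_B", "n_trees"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @property
    def colony(self) -> Colony:
        return Colony(self.colony_name, GeoPoint(self.colony_lon, self.colony_lat))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        colony = raw.pop("colony", None)
        if colony:
            raw.setdefault("colony_name", colony.get("name", "colony"))
            raw.setdefault("colony_lon", colony["lon"])
            raw.setdefault("colony_lat", colony["lat"])
        known = {f for f in cls.__dataclass_fields__}
        cfg = {k: v for k, v in raw.items() if k in known}
        return cls(**cfg)

    def validate_inputs(self) -> None:
        """Fail before any compute when declared inputs are unreadable."""
        if self.simulate:
            return
        if not self.tracks_path or not Path(self.tracks_path).exists():
            raise ConfigError(f"tracks path not readable: {self.tracks_path}")
        if not self.env_paths:
            raise ConfigError("habitat stage enabled but no environmental layer paths given")
        for season, p in self.env_paths.items():
            if not Path(p).exists():
                raise ConfigError(f"missing environmental layers for {season}: {p}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate_inputs()
    colony = config.colony
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: s for name, s in zip(STAGES, ss.spawn(len(STAGES)))}
    manifest: dict = {
        "software": f"petreltrack {__version__}",
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": {},
        "started_utc": pd.Timestamp.utcnow().isoformat(),
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    # ---- load -------------------------------------------------------------
    try:
        if config.simulate:
            bundle = synthetic.generate_bundle(np.random.SeedSequence(config.seed))
            tracks, attendance, env = bundle.tracks, bundle.attendance, bundle.env
            colony = bundle.colony
            n_dropped = 0
        else:
            tracks, n_dropped = read_tracks(config.tracks_path, config.deployments)
            attendance = (
                pd.read_csv(config.attendance_path)
                if config.attendance_path and Path(config.attendance_path).exists()
                else None
            )
            env = {s: EnvLayerSet.from_netcdf(p) for s, p in config.env_paths.items()}
        record("load", n_tracks=len(tracks), rows_dropped=n_dropped)
    except ConfigError:
        raise
    except Exception as e:  # pragma: no cover - defensive
        raise StageError("load", e) from e

    # ---- speed filter -----------------------------------------------------
    try:
        filtered = []
        removed = total = 0
        for tr in tracks:
            ftr, rep = speed_filter(tr, config.vmax_km_h, config.speed_window_h)
            filtered.append(ftr)
            removed += rep.n_removed
            total += rep.n_total
        record("filter", n_fixes=total, n_removed=removed)
    except Exception as e:
        raise StageError("filter", e) from e

    # ---- trips ------------------------------------------------------------
    try:
        all_trips = []
        for tr in filtered:
            for t in trips_mod.split_trips(
                tr, colony, config.inner_buff_km, config.min_locs, config.return_buff_km
            ):
                trips_mod.classify_trip(t, attendance, config.min_locs)
                all_trips.append(t)
        trips_table = trips_mod.trips_table(all_trips, colony)
        trips_table.to_csv(out / "trips.csv", index=False)
        summary = trips_mod.trip_summary_table(all_trips, colony)
        summary.to_csv(out / "trip_summary.csv", index=False)
        long_trips = [t for t in all_trips if t.category == trips_mod.CATEGORY_LONG]
        record(
            "trips",
            n_trips=len(all_trips),
            n_long=len(long_trips),
            n_neglect=sum(t.category == trips_mod.CATEGORY_SHORT_NEGLECT for t in all_trips),
        )
    except Exception as e:
        raise StageError("trips", e) from e

    # ---- first passage time ----------------------------------------------
    try:
        ladder = np.geomspace(config.fpt_r_min_km, config.fpt_r_max_km, config.fpt_n_radii)
        profiles = [
            fpt_mod.fpt_profile(t, colony, ladder, config.max_gap_h) for t in long_trips
        ]
        scale_km = fpt_mod.select_search_scale(profiles)
        fpt_locs, prop_foraging = fpt_mod.classify_foraging(profiles, scale_km)
        fpt_locs.to_csv(out / "fpt_locations.csv", index=False)
        per_trip = pd.DataFrame(
            {
                "trip_id": [p.trip.trip_id for p in profiles],
                "season": [p.trip.season for p in profiles],
                "peak_radius_km": [p.peak_radius_km for p in profiles],
            }
        ).merge(prop_foraging, left_on="trip_id", right_index=True, how="left")
        per_trip.to_csv(out / "fpt_trips.csv", index=False)
        season_prop = (
            fpt_locs[fpt_locs["label"] != fpt_mod.LABEL_UNLABELLED]
            .groupby("season")["label"]
            .apply(lambda s: float((s == fpt_mod.LABEL_FORAGING).mean()))
        )
        record("fpt", n_profiles=len(profiles), search_scale_km=scale_km,
               **{f"prop_foraging_{k}": round(v, 4) for k, v in season_prop.items()})
    except Exception as e:
        raise StageError("fpt", e) from e

    # ---- utilisation distributions & overlap -------------------------------
    try:
        from .geotrack import project_aeqd

        groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for key_fn, tag in (
            (lambda t: t.season, "season"),
            (lambda t: f"{t.season}_{t.year}", "season_year"),
        ):
            for t in long_trips:
                key = key_fn(t)
                x, y = project_aeqd(t.fixes["lon"].to_numpy(), t.fixes["lat"].to_numpy(), colony)
                gx, gy = groups.setdefault(key, ([], []))
                gx.append(x)
                gy.append(y)
        groups = {k: (np.concatenate(v[0]), np.concatenate(v[1])) for k, v in groups.items()}
        all_x = np.concatenate([v[0] for v in groups.values()])
        all_y = np.concatenate([v[1] for v in groups.values()])
        h = (
            config.bandwidth_km
            if config.bandwidth_km
            else spaceuse.href_bandwidth(all_x, all_y)
        )
        grid = spaceuse.GridSpec.around_points(all_x, all_y, margin_km=3 * h, cell_km=config.cell_km)
        uds = {k: spaceuse.kernel_ud(x, y, h, grid) for k, (x, y) in groups.items()}
        area_rows = []
        for k, ud in uds.items():
            for lv, c in spaceuse.volume_contours(ud, config.ud_levels).items():
                area_rows.append({"group": k, "level": lv, "area_km2": c.area_km2})
        pd.DataFrame(area_rows).to_csv(out / "ud_areas.csv", index=False)
        record("ud", n_uds=len(uds), bandwidth_km=h, grid_cells=grid.nx * grid.ny)

        seasons = sorted({t.season for t in long_trips})
        ba_rows = []
        if len(seasons) == 2:
            ba_rows.append(
                {
                    "comparison": f"between_{seasons[0]}_{seasons[1]}",
                    "ba": spaceuse.ba_overlap(uds[seasons[0]], uds[seasons[1]]),
                }
            )
        for s in seasons:
            yrs = sorted({t.year for t in long_trips if t.season == s})
            if len(yrs) == 2:
                ba_rows.append(
                    {
                        "comparison": f"within_{s}_{yrs[0]}_{yrs[1]}",
                        "ba": spaceuse.ba_overlap(
                            uds[f"{s}_{yrs[0]}"], uds[f"{s}_{yrs[1]}"]
                        ),
                    }
                )
        ba_table = pd.DataFrame(ba_rows)
        ba_table.to_csv(out / "ba_overlap.csv", index=False)
        record("overlap", n_comparisons=len(ba_rows))
    except Exception as e:
        raise StageError("ud", e) from e

    # ---- seasonal statistics ----------------------------------------------
    try:
        results = []
        inc = trips_table[
            (trips_table["category"] == trips_mod.CATEGORY_LONG)
            & (trips_table["stage"] == "incubation")
        ]
        if inc["season"].nunique() == 2:
            groups_b = [g["bearing_deg"].to_numpy() for _, g in inc.groupby("season")]
            r = seastats.watson_williams(groups_b)
            results.append(("trip_bearing", r))
        glmm_data = trips_table[trips_table["category"] == trips_mod.CATEGORY_LONG].rename(
            columns={"bird_id": "bird"}
        )
        for response in ("duration_h", "total_distance_km", "max_range_km"):
            r = seastats.gamma_glmm_lrt(glmm_data, response)
            results.append((response, r))
        pd.DataFrame(
            [
                {
                    "response": name,
                    "method": r.method,
                    "statistic": r.statistic,
                    "df": str(r.df),
                    "p_value": r.p_value,
                }
                for name, r in results
            ]
        ).to_csv(out / "test_results.csv", index=False)
        record("stats", n_tests=len(results))
    except Exception as e:
        raise StageError("stats", e) from e

    # ---- habitat selection -------------------------------------------------
    try:
        rng_hab = np.random.default_rng(stage_seeds["habitat"])
        foraging = fpt_locs[fpt_locs["label"] == fpt_mod.LABEL_FORAGING]
        used = {s: g.reset_index(drop=True) for s, g in foraging.groupby("season")}
        if len(used) != 2:
            raise hab.DesignError("need foraging locations in both seasons")
        s1, s2 = sorted(used)
        sets = {}
        for focal, other in ((s1, s2), (s2, s1)):
            uv, n_drop = hab.build_used_available(
                used[focal][["timestamp", "lon", "lat"]],
                used[other][["timestamp", "lon", "lat"]],
                env[focal],
                seed=rng_hab,
            )
            uv["season"] = focal
            sets[focal] = uv
        # between-season set: used locations of both seasons, each annotated
        # against its own season's layers
        between = pd.concat(
            [sets[s][sets[s]["role"] == "used"] for s in (s1, s2)], ignore_index=True
        )

        tables = []
        for s in (s1, s2):
            t3 = hab.group_summary_table(
                sets[s], "role", "available", "used", B=config.bootstrap_B, seed=rng_hab
            )
            t3.insert(0, "season", s)
            t3.insert(1, "contrast", "used_vs_available")
            tables.append(t3)
        t2 = hab.group_summary_table(
            between, "season", s1, s2, B=config.bootstrap_B, seed=rng_hab
        )
        t2.insert(0, "season", "both")
        t2.insert(1, "contrast", "between_seasons")
        tables.append(t2)
        pd.concat(tables, ignore_index=True).to_csv(out / "env_comparisons.csv", index=False)

        model_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in stage_seeds["habitat"].spawn(6)]
        models = {
            "between": hab.fit_selection_model(between, "season", model_seeds[0], config.n_trees),
            s1: hab.fit_selection_model(sets[s1], "role", model_seeds[1], config.n_trees),
            s2: hab.fit_selection_model(sets[s2], "role", model_seeds[2], config.n_trees),
        }
        imp = pd.DataFrame(
            {
                "between": hab.permutation_importances(models["between"], between, "season", model_seeds[3]),
                s1: hab.permutation_importances(models[s1], sets[s1], "role", model_seeds[4]),
                s2: hab.permutation_importances(models[s2], sets[s2], "role", model_seeds[5]),
            }
        )
        imp.rename_axis("variable").to_csv(out / "importances.csv")

        acc_rows = []
        for name, m in models.items():
            for cls, a in m.oob_class_accuracy.items():
                acc_rows.append({"model": name, "kind": "oob", "class": cls, "accuracy": a})
        for focal, other in ((s1, s2), (s2, s1)):
            tr_acc = hab.cross_season_transfer(models[focal], sets[other], "role")
            for cls, a in tr_acc.items():
                acc_rows.append(
                    {"model": focal, "kind": f"transfer_to_{other}", "class": cls, "accuracy": a}
                )
        pd.DataFrame(acc_rows).to_csv(out / "model_accuracies.csv", index=False)

        pd_curves = []
        for s in (s1, s2):
            c = hab.partial_dependence(models[s], sets[s], "sst_c", "used")
            c.insert(0, "season", s)
            pd_curves.append(c)
        pd.concat(pd_curves, ignore_index=True).to_csv(out / "partial_dependence_sst.csv", index=False)
        record(
            "habitat",
            n_rows={s: len(sets[s]) for s in sets},
            n_models=len(models),
        )
    except hab.DesignError as e:
        raise StageError("habitat", e) from e
    except Exception as e:
        raise StageError("habitat", e) from e

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
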
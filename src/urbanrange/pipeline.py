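"""End-to-end orchestration from a single YAML config.

A run executes a subset of stages in dependency order, writes plain-text
artifacts (CSV / GeoJSON / ASCII grids / JSON) into an output directory and
records a manifest with content hashes.  Stochastic stages derive their
seeds deterministically from the global seed and the stage name.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "dispersal", "ranges", "tfa", "glmm", "predictors", "sdm")
STAGE_DEPS = {
    "qc": (),
    "dispersal": ("qc",),
    "ranges": ("dispersal",),
    "tfa": ("ranges",),
    "glmm": ("tfa",),
    "predictors": (),
    "sdm": ("predictors",),
    "simulate": (),
}

_KNOWN_KEYS = {
    "seed", "out_dir", "fixes_csv", "nests_csv", "region_geojson", "water_geojson",
    "hdop_max", "min_satellites", "min_solar_elevation", "min_tracking_days",
    "territory_radius_m", "return_window_days", "max_age_days",
    "cluster_eps_m", "cluster_min_pts", "tfa_min_fixes", "tfa_min_period_days",
    "contour_level", "n_boot", "background_ratio", "cv_folds", "hinge_knots",
    "beta_multipliers", "simulate_n_individuals", "simulate_n_days",
    "landscape_extent_m", "landscape_cell_m", "n_presence",
}


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "runs/out"
    fixes_csv: str | None = None
    nests_csv: str | None = None
    region_geojson: str | None = None
    water_geojson: str | None = None
    hdop_max: float = 4.0
    min_satellites: int = 5
    min_solar_elevation: float = -12.0
    min_tracking_days: int = 30
    territory_radius_m: float = 1000.0
    return_window_days: int = 7
    max_age_days: int = 730
    cluster_eps_m: float = 150.0
    cluster_min_pts: int = 10
    tfa_min_fixes: int = 30
    tfa_min_period_days: int = 10
    contour_level: float = 0.5
    n_boot: int = 1000
    background_ratio: int = 10
    cv_folds: int = 10
    hinge_knots: int = 20
    beta_multipliers: tuple = (1, 2, 3, 4, 5)
    simulate_n_individuals: int = 3
    simulate_n_days: int = 120
    landscape_extent_m: float = 6000.0
    landscape_cell_m: float = 50.0
    n_presence: int = 30
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


def stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig, stages: list[str]) -> dict:
    """Execute stages in dependency order; returns the artifact manifest."""
    from . import dispersal as disp_mod
    from . import glmm as glmm_mod
    from . import maxent as mx
    from . import ranges as ranges_mod
    from . import synthetic as syn
    from . import tfa as tfa_mod
    from . import tracking as trk
    from .geo import write_geojson_features
    from .habitat import Raster

    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    ordered = [s for s in STAGES if s in stages]
    for s in ordered:
        for dep in STAGE_DEPS[s]:
            if dep not in ordered and s != "simulate":
                # the dependency may be satisfied by existing artifacts
                if not _artifacts_exist(config, dep):
                    raise RuntimeError(f"stage {s!r} requires outputs of stage {dep!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    params_used = {k: v for k, v in vars(config).items() if k != "extras"}

    state: dict = {}

    if "simulate" in ordered:
        seed = stage_seed(config.seed, "simulate")
        frames = []
        nests = []
        for i in range(config.simulate_n_individuals):
            scen = syn.TrackScenario(
                individual_id=f"SYN{i:02d}",
                nest=(2000.0 + 800.0 * i, 2000.0 + 500.0 * i),
                onset_day=25 + 5 * i,
                n_days=config.simulate_n_days,
                seed=seed + i,
            )
            track, _ = syn.simulate_track(scen)
            frames.append(track.to_frame())
            lonn, latn = track.projection.inverse(*scen.nest)
            nests.append(
                {"individual_id": scen.individual_id, "nest_lon": float(lonn),
                 "nest_lat": float(latn), "hatch_date": scen.hatch_date.isoformat()}
            )
        fixes_path = out / "synthetic_fixes.csv"
        pd.concat(frames, ignore_index=True).drop(columns=["x", "y"]).to_csv(
            fixes_path, index=False
        )
        nests_path = out / "synthetic_nests.csv"
        pd.DataFrame(nests).to_csv(nests_path, index=False)
        written += [fixes_path, nests_path]
        config.fixes_csv = str(fixes_path)
        config.nests_csv = str(nests_path)

    if "qc" in ordered:
        if not config.fixes_csv:
            raise RuntimeError("stage 'qc' requires fixes_csv (or run 'simulate')")
        tracks = trk.read_fixes(config.fixes_csv)
        proj = next(iter(tracks.values())).projection
        if config.nests_csv:
            trk.attach_nests(tracks, config.nests_csv, proj)
        tracks = {
            k: trk.daylight_filter(
                trk.qc_filter(t, config.hdop_max, config.min_satellites),
                config.min_solar_elevation,
            )
            for k, t in tracks.items()
        }
        if config.region_geojson:
            from .geo import project_polygon, read_geojson_polygons

            region = read_geojson_polygons(config.region_geojson)[0]
            region = project_polygon(proj, region)
            tracks = trk.clip_and_qualify(tracks, region, config.min_tracking_days)
        else:
            tracks = {
                k: t for k, t in tracks.items()
                if len({f.date for f in t.fixes}) >= config.min_tracking_days
            }
        qc_path = Path(config.out_dir) / "fixes_qc.csv"
        trk.write_fixes(tracks, qc_path)
        written.append(qc_path)
        state["tracks"] = tracks

    if "dispersal" in ordered:
        tracks = state["tracks"]
        rows = []
        kept = {}
        for k, t in tracks.items():
            res = disp_mod.detect_onset(
                t, radius=config.territory_radius_m, return_window=config.return_window_days
            )
            if res.onset_date is not None:
                tt = disp_mod.dispersal_window(t, res, config.max_age_days)
                if tt.fixes:
                    kept[k] = tt
            rows.append(
                {"individual_id": k,
                 "onset_date": res.onset_date.isoformat() if res.onset_date else "",
                 "n_fixes_retained": len(kept[k].fixes) if k in kept else 0}
            )
        p = out / "dispersal.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
        state["tracks"] = kept

    if "ranges" in ordered:
        rows = []
        feats = []
        cfrs = {}
        for k, t in state["tracks"].items():
            if len(t) < 20:
                log.warning("individual %s skipped in ranges: too few fixes", k)
                continue
            models = ranges_mod.fit_candidates(t)
            best = ranges_mod.select_model(models)
            est = ranges_mod.akde(t, best)
            cont = ranges_mod.contour(est, config.contour_level)
            cfrs[k] = (t, cont)
            for m in models:
                rows.append(
                    {"individual_id": k, "kind": m.kind, "sigma2": m.sigma2,
                     "tau_pos": m.tau_pos, "tau_vel": m.tau_vel, "loglik": m.loglik,
                     "aicc": m.aicc, "selected": m.kind == best.kind}
                )
            for poly in cont.polygons:
                feats.append(
                    {"geometry": poly,
                     "properties": {"individual_id": k, "area_km2": cont.area / 1e6,
                                    "ci_low": cont.ci_low / 1e6, "ci_high": cont.ci_high / 1e6,
                                    "model_kind": best.kind, "n_area": est.n_area}}
                )
        p1 = out / "movement_models.csv"
        pd.DataFrame(rows).to_csv(p1, index=False)
        p2 = out / "cfr_contours.geojson"
        write_geojson_features(p2, feats)
        written += [p1, p2]
        state["cfrs"] = cfrs

    if "tfa" in ordered:
        rows = []
        feats = []
        pop_raster = state.get("pop_density_raster")
        if pop_raster is None and state["cfrs"]:
            # cover the fix extent with a synthetic density surface so the
            # covariate (and the downstream GLMMs) can be exercised end to end
            pop_raster = _synthetic_pop_raster(state["cfrs"], stage_seed(config.seed, "popdens"))
        for k, (t, cont) in state["cfrs"].items():
            clusters = tfa_mod.extract_tfas(k, t.fixes, cont.polygons,
                                            pop_density=pop_raster,
                                            eps=config.cluster_eps_m,
                                            min_pts=config.cluster_min_pts)
            for i, c in enumerate(clusters):
                rows.append(
                    {"individual_id": k, "tfa_id": f"{k}-{i}", "n_fixes": len(c.fixes),
                     "timespan_days": c.timespan_days, "area_ha": c.area_ha,
                     "habitat_label": c.habitat_label,
                     "mean_pop_density": c.mean_pop_density}
                )
                feats.append({"geometry": c.mcp, "properties": rows[-1]})
        p1 = out / "tfas.csv"
        pd.DataFrame(rows).to_csv(p1, index=False)
        p2 = out / "tfas.geojson"
        write_geojson_features(p2, feats)
        written += [p1, p2]
        state["tfa_table"] = pd.DataFrame(rows)

    if "glmm" in ordered:
        table = state.get("tfa_table")
        if table is None or table.empty or table["mean_pop_density"].isna().all():
            log.warning("glmm stage skipped: no TFA rows with covariates")
        else:
            seed = stage_seed(config.seed, "glmm")
            reports = {}
            for family, resp in (("poisson", "timespan_days"), ("gaussian", "area_ha")):
                null = glmm_mod.fit_glmm(table, resp, None, "individual_id", family)
                alt = glmm_mod.fit_glmm(table, resp, "mean_pop_density", "individual_id", family)
                lrt = glmm_mod.bootstrap_lrt(null, alt, n_boot=config.n_boot, seed=seed)
                reports[family] = {
                    "family": family, "beta": list(alt.beta), "sigma2_u": alt.sigma2_u,
                    "lrt_statistic": lrt.statistic, "df": lrt.df, "p_boot": lrt.p_boot,
                    "n_boot": lrt.n_boot, "seed": seed,
                }
                dens = table["mean_pop_density"].to_numpy(dtype=float)
                grid = np.linspace(max(dens.min(), 0.5), dens.max(), 50)
                curve = glmm_mod.predict_with_pe(alt, grid)
                pc = out / f"prediction_curve_{family}.csv"
                curve.to_csv(pc, index=False)
                written.append(pc)
            p = out / "glmm_report.json"
            p.write_text(json.dumps(reports, indent=1))
            written.append(p)

    if "predictors" in ordered or "sdm" in ordered:
        seed = stage_seed(config.seed, "landscape")
        scen = syn.LandscapeScenario(
            extent=(config.landscape_extent_m, config.landscape_extent_m),
            cell=config.landscape_cell_m, seed=seed,
        )
        rasters, habitat_polys, water_polys = syn.simulate_landscape(scen)
        state["landscape"] = (scen, rasters, habitat_polys, water_polys)
        if "predictors" in ordered:
            for name, r in rasters.items():
                p = out / f"predictor_{name}.asc"
                r.write_ascii(p)
                written.append(p)

    if "sdm" in ordered:
        scen, rasters, _, water_polys = state["landscape"]
        seed = stage_seed(config.seed, "sdm")
        pts, _truth = syn.simulate_breeding_sites(
            rasters, {"tree_cover": 3.0, "habitat_type:4": 1.5}, config.n_presence, seed
        )
        region = syn.region_polygon(scen)
        bg = mx.sample_background(region, water_polys, len(pts),
                                  config.background_ratio, seed + 1)
        from .habitat import extract_predictors

        scales = {n: "local" for n in rasters}
        pres_tab = extract_predictors(rasters, scales, pts)
        bg_tab = extract_predictors(rasters, scales, bg)

        # collinearity screen on continuous candidates, scored by univariate CV-AUC
        from .habitat import collinearity_filter

        continuous = [c for c in pres_tab.columns if not c.startswith("habitat_type_")]
        scores = mx.univariate_cv_auc(pres_tab[continuous], bg_tab[continuous],
                                      k=min(5, config.cv_folds), seed=seed + 3)
        kept = collinearity_filter(pd.concat([pres_tab[continuous], bg_tab[continuous]],
                                             ignore_index=True), scores)
        keep_cols = kept + [c for c in pres_tab.columns if c.startswith("habitat_type_")]
        pres_tab, bg_tab = pres_tab[keep_cols], bg_tab[keep_cols]

        model, best, grid = mx.cross_validate(
            pres_tab, bg_tab, k=min(config.cv_folds, len(pts)),
            seed=seed + 2, hinge_knots=config.hinge_knots,
            multipliers=tuple(config.beta_multipliers),
        )
        p1 = out / "model_grid.csv"
        pd.DataFrame(
            [{"feature_combo": r.feature_combo, "beta_multiplier": r.beta_multiplier,
              "mean_auc": r.auc, "tss": r.tss, "threshold": r.threshold} for r in grid]
        ).to_csv(p1, index=False)
        written.append(p1)

        ref = rasters["tree_cover"]
        cx, cy = ref.cell_centres()
        xs, ys = np.meshgrid(cx, cy)
        cells = np.column_stack([xs.ravel(), ys.ravel()])
        cell_tab = _cell_predictor_table(rasters, cells)
        suit_vals = mx.predict_table(model, cell_tab).reshape(ref.values.shape)
        suit = Raster(ref.origin, ref.cell_size, suit_vals, kind="continuous")
        p2 = out / "suitability.asc"
        suit.write_ascii(p2)
        written.append(p2)

        pres_cell_tab = _cell_predictor_table(rasters, pts)
        thr, _, _ = mx.max_sss_threshold(
            mx.predict_table(model, pres_cell_tab), suit_vals.ravel()
        )
        binary, report = mx.binarize_and_account(
            suit, thr, habitat=rasters["habitat_type"], occupied_nests=pts
        )
        p3 = out / "suitability_binary.asc"
        binary.write_ascii(p3)
        p4 = out / "area_report.json"
        p4.write_text(json.dumps(
            {"total_suitable_km2": report.total_suitable_km2,
             "by_habitat_class_km2": {str(k): v for k, v in report.by_habitat_class_km2.items()},
             "unoccupied_suitable_km2": report.unoccupied_suitable_km2,
             "occupied_buffer_radius_m": report.occupied_buffer_radius_m}, indent=1))
        written += [p3, p4]

    manifest = {
        "created_utc": dt.datetime.now(dt.timezone.utc).isoformat(),
        "stages": ordered,
        "seed": config.seed,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in params_used.items()},
        "artifacts": {str(p.relative_to(out)): _hash_file(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _cell_predictor_table(rasters, points) -> pd.DataFrame:
    """Point-sample every raster (no focal smoothing) into a predictor table."""
    from .habitat import _cell_value

    cols = {}
    for name, r in rasters.items():
        vals = np.array([_cell_value(r, p) for p in np.asarray(points)])
        if r.kind == "categorical":
            levels = sorted(int(c) for c in np.unique(r.values))
            for lev in levels[1:]:
                cols[f"{name}_{lev}"] = (vals == lev).astype(float)
        else:
            cols[name] = vals.astype(float)
    return pd.DataFrame(cols)


def _synthetic_pop_raster(cfrs: dict, seed: int):
    """Smooth positive density surface spanning all fixes (100 m cells)."""
    from scipy.ndimage import gaussian_filter

    from .habitat import Raster

    xs, ys = [], []
    for t, _ in cfrs.values():
        xy = t.xy
        xs += [xy[:, 0].min(), xy[:, 0].max()]
        ys += [xy[:, 1].min(), xy[:, 1].max()]
    cell = 100.0
    pad = 500.0
    x0, x1 = min(xs) - pad, max(xs) + pad
    y0, y1 = min(ys) - pad, max(ys) + pad
    n_cols = max(int(np.ceil((x1 - x0) / cell)), 4)
    n_rows = max(int(np.ceil((y1 - y0) / cell)), 4)
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.normal(size=(n_rows, n_cols)), sigma=5.0, mode="wrap")
    sd = f.std() or 1.0
    vals = np.clip(60.0 + 30.0 * f / sd, 0.5, None)
    return Raster((x0, y0 + n_rows * cell), cell, vals, kind="continuous")


def _artifacts_exist(config: RunConfig, stage: str) -> bool:
    out = Path(config.out_dir)
    markers = {
        "qc": "fixes_qc.csv", "dispersal": "dispersal.csv",
        "ranges": "cfr_contours.geojson", "tfa": "tfas.csv",
        "predictors": "predictor_tree_cover.asc",
    }
    marker = markers.get(stage)
    return marker is not None and (out / marker).exists()
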
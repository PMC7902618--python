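"""End-to-end pipeline driver.

Runs simulate -> reconstruct -> disturb -> loss -> train -> interpret ->
predict -> trends -> ovi on a synthetic domain, writing each stage's
outputs plus a manifest (config, seeds, file hashes) into a run directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import biomass_recon as br
from . import disturbance_loss as dl
from . import interpretation as interp
from . import io as fio
from . import model_training as mt
from . import ovi as ovi_mod
from . import spacetime as st
from . import synth
from .config import PipelineConfig
from .features import DYNAMIC_FEATURES, FEATURES, categories_map


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _ice_slope_grids(model, fields: st.PredictorFields, current_years,
                     cover_min: float, grid_size: int = 50):
    """Per-cell ICE slopes for every model feature, on current conditions."""
    frozen = fields.climate_mean(list(current_years))
    grids = {}
    for name in model.features:
        if name in fields.static:
            grids[name] = fields.static[name].values
        else:
            grids[name] = frozen[name]
    cover = fields.cover()
    mask = cover >= cover_min
    X = np.column_stack([grids[f][mask] for f in model.features])
    slopes = {}
    for k, name in enumerate(model.features):
        lo, hi = model.feature_ranges[name]
        gvals = np.linspace(lo, hi, grid_size)
        rep = np.repeat(X[None, :, :], grid_size, axis=0)
        rep[:, :, k] = gvals[:, None]
        preds = model.predict(rep.reshape(-1, X.shape[1])) \
            .reshape(grid_size, -1)
        gc = gvals - gvals.mean()
        denom = (gc ** 2).sum()
        s = (gc[:, None] * (preds - preds.mean(axis=0))).sum(axis=0) / denom \
            if denom > 0 else np.zeros(preds.shape[1])
        grid = np.full(cover.shape, np.nan)
        grid[mask] = s
        slopes[name] = grid
    return slopes, mask


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> Path:
    """Execute every stage; returns the run directory."""
    cfg = config
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yml")
    manifest: dict = {"stages": {}, "seeds": cfg.seeds.model_dump()}
    ctx: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("reconstruct", _stage_reconstruct),
        ("disturb", _stage_disturb),
        ("loss", _stage_loss),
        ("train", _stage_train),
        ("interpret", _stage_interpret),
        ("predict", _stage_predict),
        ("trends", _stage_trends),
        ("ovi", _stage_ovi),
    ]
    for name, fn in stages:
        try:
            written = fn(cfg, ctx, out)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {
            "outputs": {str(p.relative_to(out)): fio.file_sha256(p)
                        for p in written}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


# --------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, ctx: dict, out: Path):
    truths = {d: synth.default_truth(d, seed=cfg.seeds.simulate + i)
              for i, d in enumerate(cfg.disturbances)}
    landscape = synth.generate_landscape(cfg.seeds.simulate, cfg.nx, cfg.ny)
    merged_trends: dict[str, float] = {}
    for t in truths.values():
        merged_trends.update(t.climate_trends)
    climate_truth = synth.GeneratorTruth(disturbance="fire",
                                         climate_trends=merged_trends)
    y0, y1 = cfg.years_climate
    climate = synth.generate_climate(cfg.seeds.simulate + 100,
                                     range(y0, y1 + 1), climate_truth,
                                     landscape=landscape)
    ctx.update(truths=truths, landscape=landscape, climate=climate)
    return [fio.write_dataset(landscape, out / "landscape.nc"),
            fio.write_dataset(climate, out / "climate.nc"),
            fio.write_truth(truths, out / "truth.json")]


def _stage_reconstruct(cfg: PipelineConfig, ctx: dict, out: Path):
    landscape = ctx["landscape"]
    layers = synth.landscape_layers(landscape)
    y0, y1 = cfg.years_biomass
    stack = br.reconstruct_stack(landscape["b2010"].values, layers,
                                 years=range(y0, y1 + 1),
                                 resolution=landscape.attrs["resolution"])
    ctx["stack"] = stack
    return [fio.write_stack(stack, out / "stack.nc")]


def _stage_disturb(cfg: PipelineConfig, ctx: dict, out: Path):
    stack = ctx["stack"]
    n_each = max(1, cfg.n_patches // len(cfg.disturbances))
    all_patches, truth_tables = [], []
    for i, d in enumerate(cfg.disturbances):
        patches, stack, table = synth.generate_disturbances(
            cfg.seeds.simulate + 200 + i, ctx["truths"][d], stack,
            ctx["landscape"], ctx["climate"], n_patches=n_each,
            dynamic_lag=cfg.dynamic_lag)
        all_patches.extend(patches)
        truth_tables.append(table.assign(type=d))
    ctx["stack"] = stack
    ctx["patches"] = all_patches
    ctx["patch_truth"] = pd.concat(truth_tables, ignore_index=True)
    p1 = fio.write_patches(all_patches, out / "patches.geojson")
    p2 = out / "patch_truth.csv"
    ctx["patch_truth"].to_csv(p2, index=False)
    p3 = fio.write_stack(stack, out / "stack_disturbed.nc")
    return [p1, p2, p3]


def _stage_loss(cfg: PipelineConfig, ctx: dict, out: Path):
    records = dl.build_loss_records(
        ctx["stack"], ctx["patches"], ctx["landscape"], ctx["climate"],
        lags=cfg.lags.as_dict(), bl_min=cfg.thresholds.bl_min,
        dynamic_lag=cfg.dynamic_lag)
    if records.empty:
        raise ValueError("no retained loss records")
    ctx["records"] = records
    path = out / "records.csv"
    records.to_csv(path, index=False)
    return [path]


def _stage_train(cfg: PipelineConfig, ctx: dict, out: Path):
    feature_cols = list(FEATURES)
    models, reports, splits = {}, {}, {}
    written = []
    model_dir = out / "models"
    for d in cfg.disturbances:
        recs = ctx["records"][ctx["records"]["type"] == d]
        recs = mt.impute_missing(recs, feature_cols)
        train, test = mt.pc_bin_split(
            recs, feature_cols, seed=cfg.seeds.split,
            n_bins=cfg.thresholds.pc_bins,
            min_records=cfg.thresholds.min_bin)
        if len(train) < 20 or len(test) < 10:
            # sparse-record fallback: the PC-space resampling needs record
            # counts well above the occupied-lattice size; below that we
            # train on the year-stratified record split directly
            mask = mt.year_stratified_mask(recs, cfg.seeds.split)
            train = mt.as_binned(recs[mask], feature_cols)
            test = mt.as_binned(recs[~mask], feature_cols)
        Q = mt.select_features(train, test, seed=cfg.seeds.train,
                               n_trees=cfg.thresholds.n_trees,
                               threshold=cfg.thresholds.spearman)
        model = mt.fit(train, Q, seed=cfg.seeds.train, disturbance=d,
                       n_trees=cfg.thresholds.n_trees,
                       n_search=cfg.n_hyperparam_draws, test=test)
        report = mt.validate(model, test)
        models[d] = {"all": model}
        if cfg.per_pft_models:
            from .errors import InsufficientDataError
            from .features import PFTS
            for pft in PFTS:
                try:
                    pm = mt.fit(train, Q, seed=cfg.seeds.train, pft=pft,
                                disturbance=d,
                                n_trees=cfg.thresholds.n_trees,
                                n_search=0, test=test)
                except InsufficientDataError:
                    continue
                models[d][pft] = pm
                written.append(fio.write_model(pm, model_dir))
        reports[d] = report
        splits[d] = (train, test)
        written.append(fio.write_model(model, model_dir, report=report))
        written.append(model_dir / f"{d}_all.json")
    ctx.update(models=models, reports=reports, splits=splits)
    return written


def _stage_interpret(cfg: PipelineConfig, ctx: dict, out: Path):
    written = []
    cat_rows, h_rows, pdp_rows = [], [], []
    for d in cfg.disturbances:
        model = ctx["models"][d]["all"]
        train, _ = ctx["splits"][d]
        data = train.bins
        top = sorted(model.features,
                     key=lambda n: -model.importances.get(n, 0.0))
        top = top[:cfg.interpret_top_k]
        for f in top:
            curve = interp.pdp(model, f, data, centre=True,
                               grid_size=cfg.thresholds.pdp_grid)
            for g, v in zip(curve.grid, curve.pd_values):
                pdp_rows.append({"disturbance": d, "feature": f,
                                 "x": g, "pd": v})
        pairwise = interp.interaction_matrix(model, data, features=top,
                                             seed=cfg.seeds.interpret)
        for (a, b), h in pairwise.items():
            h_rows.append({"disturbance": d, "feature_i": a, "feature_j": b,
                           "h": h})
        cats = categories_map(model.features)
        cm = interp.category_interaction_means(pairwise, cats)
        cm_long = cm.stack().rename("mean_h").reset_index()
        cm_long.insert(0, "disturbance", d)
        cat_rows.append(cm_long)
        if pairwise:
            (a, b), _h = max(pairwise.items(), key=lambda kv: kv[1])
            dp = interp.delta_p(model, a, b, data,
                                seed=cfg.seeds.interpret)
            h_rows.append({"disturbance": d, "feature_i": a, "feature_j": b,
                           "h": _h, "delta_p": dp})
    for name, df in (("pdp_curves.csv", pd.DataFrame(pdp_rows)),
                     ("pairwise_h.csv", pd.DataFrame(h_rows)),
                     ("category_h.csv", pd.concat(cat_rows, ignore_index=True))):
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)
    return written


def _current_years(cfg: PipelineConfig):
    return range(cfg.current_window[0], cfg.current_window[1] + 1)


def _stage_predict(cfg: PipelineConfig, ctx: dict, out: Path):
    landscape, climate = ctx["landscape"], ctx["climate"]
    from .features import PFTS
    fields = st.PredictorFields(
        static=landscape, climate=climate,
        pft_fractions={p: landscape[f"pft_{p}"] for p in PFTS})
    ctx["fields"] = fields
    y0, y1 = cfg.years_climate
    written = []
    summaries = {}
    vulns, currents = {}, {}
    for d in cfg.disturbances:
        models = ctx["models"][d]
        if "all" not in models and not cfg.per_pft_models:
            raise ValueError(f"no pooled model for {d}")
        use = models if cfg.per_pft_models and len(models) > 1 \
            else {"all": models["all"]}
        vuln = st.predict_series(use, fields, range(y0, y1 + 1),
                                 current_window=_current_years(cfg),
                                 cover_min=cfg.thresholds.cover_mask)
        current = vuln["pbl"].sel(year=list(_current_years(cfg))).mean("year")
        vulns[d], currents[d] = vuln, current

        weights = np.where(vuln["forest_mask"].values, fields.cover(), 0.0)
        mean, ci = st.zonal_stats(current.values, weights,
                                  n_boot=cfg.thresholds.n_boot,
                                  seed=cfg.seeds.predict)
        env = st.envelope_mask(fields, ctx["records"][
            ctx["records"]["type"] == d])
        mean_env, ci_env = st.zonal_stats(
            np.where(env, current.values, np.nan), weights,
            n_boot=cfg.thresholds.n_boot, seed=cfg.seeds.predict)

        model = models["all"]
        slopes, mask = _ice_slope_grids(model, fields, _current_years(cfg),
                                        cfg.thresholds.cover_mask,
                                        grid_size=cfg.thresholds.pdp_grid)
        cats = categories_map(model.features)
        zgrids = {c: np.full(mask.shape, np.nan) for c in ("forest", "climate",
                                                           "landscape")}
        flat = {n: g[mask] for n, g in slopes.items()}
        n_cells = int(mask.sum())
        z_stack = np.full((3, n_cells), np.nan)
        for i_cell in range(n_cells):
            z = interp.z_marg({n: flat[n][i_cell] for n in flat}, cats)
            for k, c in enumerate(("forest", "climate", "landscape")):
                z_stack[k, i_cell] = z[c]
        for k, c in enumerate(("forest", "climate", "landscape")):
            zgrids[c][mask] = z_stack[k]

        ds = vuln.copy()
        ds["current"] = current
        ds["envelope_mask"] = (("y", "x"), env)
        for c, g in zgrids.items():
            ds[f"z_marg_{c}"] = (("y", "x"), g)
        path = out / f"vuln_{d}.nc"
        written.append(fio.write_dataset(ds, path))
        summaries[d] = {
            "current_mean": mean, "current_ci": ci,
            "current_mean_envelope": mean_env, "current_ci_envelope": ci_env,
            "selected_features": model.features,
            "validation": ctx["reports"][d].to_dict(),
        }
    ctx.update(vulns=vulns, currents=currents, weights=weights)
    path = out / "prediction_summary.json"
    path.write_text(json.dumps(summaries, indent=1))
    written.append(path)
    return written


def _stage_trends(cfg: PipelineConfig, ctx: dict, out: Path):
    written = []
    trends = {}
    for d in cfg.disturbances:
        vuln = ctx["vulns"][d]
        tg = st.trend_grid(vuln)
        model = ctx["models"][d]["all"]
        K = [f for f in model.features
             if f in DYNAMIC_FEATURES and FEATURES[f].category == "climate"]
        if K:
            y0, y1 = cfg.years_climate
            attr = st.factorial_attribution(
                {"all": model}, ctx["fields"], K, range(y0, y1 + 1),
                current_window=_current_years(cfg),
                cover_min=cfg.thresholds.cover_mask)
            tg = xr.merge([tg, attr])
        trends[d] = tg
        written.append(fio.write_dataset(tg, out / f"trend_{d}.nc"))
    ctx["trends"] = trends
    return written


def _stage_ovi(cfg: PipelineConfig, ctx: dict, out: Path):
    currents = ctx["currents"]
    grids = [currents[d].values for d in cfg.disturbances]
    ovi_current = ovi_mod.combine(grids)

    # domain-level cross-check on the zonal means
    weights = ctx["weights"]
    means = {}
    for d in cfg.disturbances:
        m, _ = st.zonal_stats(currents[d].values, weights,
                              n_boot=cfg.thresholds.n_boot,
                              seed=cfg.seeds.predict)
        means[d] = m
    shares = ovi_mod.contributions(means)

    stack = ctx["stack"]
    biomass_now = stack.layer(stack.years[-1])
    forest_mask = ctx["vulns"][cfg.disturbances[0]]["forest_mask"].values
    abs_grid, abs_total = ovi_mod.absolute_loss(ovi_current, biomass_now,
                                                mask=forest_mask)

    years = ctx["vulns"][cfg.disturbances[0]]["year"].values
    series = np.stack([
        ovi_mod.combine([ctx["vulns"][d]["pbl"].sel(year=y).values
                         for d in cfg.disturbances])
        for y in years])
    ovi_vuln = xr.Dataset({"pbl": (("year", "y", "x"), series)},
                          coords={"year": years})
    ovi_trend = st.trend_grid(ovi_vuln)
    sti = ovi_mod.spacetime_index(ovi_current, ovi_trend["slope"].values,
                                  mask=forest_mask)

    ds = xr.Dataset({
        "ovi_current": (("y", "x"), ovi_current),
        "ovi_trend": (("y", "x"), ovi_trend["slope"].values),
        "ovi_trend_p": (("y", "x"), ovi_trend["p_value"].values),
        "absolute_loss": (("y", "x"), abs_grid),
        "spacetime_index": (("y", "x"), sti),
    })
    p1 = fio.write_dataset(ds, out / "ovi.nc")
    ovi_mean, ovi_ci = st.zonal_stats(ovi_current, weights,
                                      n_boot=cfg.thresholds.n_boot,
                                      seed=cfg.seeds.predict)
    summary = {
        "disturbance_means": means,
        "ovi_mean": ovi_mean, "ovi_ci": ovi_ci,
        "contributions_pct": shares,
        "absolute_loss_total_t": abs_total,
    }
    p2 = out / "ovi_summary.json"
    p2.write_text(json.dumps(summary, indent=1))
    ctx["ovi_summary"] = summary
    return [p1, p2]
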
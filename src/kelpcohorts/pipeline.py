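"""End-to-end orchestration: environment -> algal states -> cohorts -> survival -> models.

``run_pipeline`` consumes a configuration mapping (typically parsed from a
YAML file) that either names input CSV paths or carries a ``simulate`` block,
runs every stage with the configured parameters, and writes plain CSV/JSON
outputs plus a manifest with a config hash so reruns are diffable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import algal_states, cohorts as coh, core_data, environment as env, modeling, simulate, survival

log = logging.getLogger("kelpcohorts")

DEFAULT_CONFIG = {
    "seed": 0,
    "k_states": 5,
    "gap_b": 20,
    "dominance_threshold": 0.4,
    "persistence": 1.0,
    "min_gap": 1.0,
    "max_pulse": 1.5,
    "lifespan_convention": "midpoint",
    "covariate_quantile": 0.80,
    "wave_threshold": 6800.0,
    "heat_threshold": 18.0,
    "mortality_min_n": 5,
}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _simulate_inputs(config: dict):
    simblock = dict(config.get("simulate", {}))
    schedule = simblock.pop("schedule", None)
    sim_cfg = simulate.SimulationConfig(seed=int(config["seed"]), **simblock)
    if schedule is not None:
        sim_cfg.schedule = [simulate.DisturbanceEvent(**ev) for ev in schedule]
    forcing = simulate.simulate_forcing(sim_cfg)
    census_parts, plants, depths = [], [], {}
    for i in range(sim_cfg.n_sites):
        c, p, _ = simulate.simulate_site(sim_cfg, i, forcing=forcing)
        census_parts.append(c)
        plants.extend(p)
        depths[c["site_id"].iloc[0]] = sim_cfg.depths[i % len(sim_cfg.depths)]
    census = core_data.validate_census(pd.concat(census_parts, ignore_index=True))
    return census, plants, forcing[0], forcing[1], depths


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    stage = "inputs"
    try:
        if "simulate" in cfg:
            census, plants, temp, waves, depths = _simulate_inputs(cfg)
        else:
            census = core_data.load_census(cfg["census_path"])
            plants = core_data.load_plants(cfg["plants_path"], dialect=cfg.get("plants_dialect", "long"))
            temp = core_data.load_env_series(cfg["temperature_path"], "temperature")
            waves = core_data.load_env_series(cfg["waves_path"], "wave")
            depths = cfg.get("site_depths", {})
        log.info("inputs: %d census rows, %d plants", len(census), len(plants))

        stage = "environment"
        temp_filled, long_gaps = env.interpolate_gaps(temp)
        anomalies = env.seasonal_detrend(temp_filled)
        weekly = env.weekly_decimate(waves)
        log.info("environment: %d long gaps left missing, %d weeks", len(long_gaps), len(weekly))

        stage = "algal states"
        guilds = algal_states.pool_guilds(census)
        scaled, scale_params = algal_states.scale_features(guilds)
        assignments, medoids = algal_states.cluster_states(scaled, k=int(cfg["k_states"]), seed=seed)
        labels = algal_states.label_states(medoids) if int(cfg["k_states"]) == 5 else None
        timeline = algal_states.state_timeline(assignments, labels)
        shifts = algal_states.detect_state_shifts(
            timeline, cfg["dominance_threshold"], cfg["persistence"])

        stage = "cohorts"
        conv = cfg["lifespan_convention"]
        all_rows, roster_rows, site_windows, site_rosters = [], [], {}, {}
        for site_id in sorted({p.site_id for p in plants}):
            site_plants = [p for p in plants if p.site_id == site_id]
            windows = coh.detect_cohort_windows(
                [p.recruit_date for p in site_plants], site_id,
                max_pulse=cfg["max_pulse"], min_gap=cfg["min_gap"])
            rosters, unassigned = coh.assign_plants(windows, site_plants)
            if unassigned:
                log.warning("%s: %d unassigned plants", site_id, len(unassigned))
            site_windows[site_id] = windows
            site_rosters[site_id] = rosters
            blended = coh.detect_blending(windows, rosters, convention=conv)
            for i, w in enumerate(windows):
                roster = rosters[w.cohort_id]
                if not roster:
                    continue
                label = coh.classify_pulse(
                    roster, w,
                    prev_window=windows[i - 1] if i > 0 else None,
                    next_window=windows[i + 1] if i + 1 < len(windows) else None,
                    min_gap=cfg["min_gap"])
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row = coh.cohort_parameters(
                        w, roster, census, scaled, temp_filled, weekly,
                        all_windows=windows, all_rosters=rosters,
                        depth=float(depths.get(site_id, np.nan)),
                        convention=conv, covariate_quantile=cfg["covariate_quantile"])
                row["pulsed"] = label
                row["blended"] = blended[w.cohort_id]
                row["mortality_cause"] = coh.attribute_mortality(
                    roster, temp_filled, weekly, census[census["site_id"] == site_id],
                    heat_threshold=cfg["heat_threshold"], wave_threshold=cfg["wave_threshold"],
                    min_n=int(cfg["mortality_min_n"]), convention=conv)
                all_rows.append(row)
                for p in roster:
                    roster_rows.append({"plant_id": p.plant_id, "cohort_id": w.cohort_id})
        params = coh.cohort_parameter_table(all_rows)
        log.info("cohorts: %d cohorts from %d plants", len(params), len(plants))

        stage = "survival"
        lt = core_data.add_lifespans(plants, convention=conv)
        curves = survival.pooled_site_curves(lt, "site_id")
        pooled = survival.km_fit(lt["duration"].to_numpy(), lt["event"].to_numpy())
        pooled_q = {p: survival.km_quantile(pooled, p) for p in (0.25, 0.5, 0.75, 0.95)}

        stage = "modeling"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            models = {}
            dead = params[~params["alive"].astype(bool)]
            if len(dead) >= 30:
                models["size"] = modeling.CohortSizeModel.from_frame(params).fit()
                models["longevity"] = modeling.CohortLongevityModel.from_frame(params).fit()
            factor_cols = ["N", "singles", "PA", "juveniles_1yr", "Ad", "life_mn", "st_max_mn"]
            usable = params.dropna(subset=[c for c in factor_cols if c in params.columns])
            factor = None
            if len(usable) >= 10:
                try:
                    factor = modeling.factor_model(usable[factor_cols], n_factors=2, seed=seed)
                except (ValueError, RuntimeError) as e:
                    log.warning("factor analysis skipped: %s", e)
            trends = modeling.trend_tests(params) if len(params) >= 10 else None
    except Exception as e:  # noqa: BLE001 - abort names the failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    # ---- demographic-event summary (trickled/pulsed, blending, causes) ----
    summary = {
        "n_plants": int(len(plants)),
        "n_cohorts": int(len(params)),
        "trickled_fraction": float((params["pulsed"] == "trickled").mean()) if len(params) else np.nan,
        "pulsed_fraction": float((params["pulsed"] == "pulsed").mean()) if len(params) else np.nan,
        "blended_fraction": float(params["blended"].mean()) if len(params) else np.nan,
        "mortality_causes": params["mortality_cause"].value_counts(normalize=True).round(4).to_dict()
        if len(params) else {},
        "pooled_km_quantiles_yr": {str(k): v for k, v in pooled_q.items()},
        "max_lifespan_yr": float(lt["duration"].max()),
        "n_censored": int((~lt["event"]).sum()),
    }

    # ---- write bundle ----
    header = f"# config_hash={config_hash(cfg)}\n"

    def _write(df: pd.DataFrame, name: str):
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)

    _write(timeline, "state_timeline.csv")
    _write(shifts, "state_shifts.csv")
    _write(medoids, "state_medoids.csv")
    _write(params, "cohort_parameters.csv")
    _write(pd.DataFrame(roster_rows), "cohort_rosters.csv")
    _write(pooled.to_frame(), "survival_pooled.csv")
    for key, curve in curves.items():
        _write(curve.to_frame(), f"survival_{key}.csv")
    if factor is not None:
        _write(factor.loadings.reset_index(names="parameter"), "factor_loadings.csv")
        summary["factor_variance_shares"] = [round(float(v), 4) for v in factor.variance_share]
    if "size" in models:
        _write(models["size"].params_table, "model_size_parametric.csv")
        _write(models["size"].smooth_table, "model_size_smooths.csv")
        _write(models["longevity"].params_table, "model_longevity_parametric.csv")
        _write(models["longevity"].smooth_table, "model_longevity_smooths.csv")
        summary["size_deviance_explained"] = models["size"].deviance_explained
        summary["longevity_deviance_explained"] = models["longevity"].deviance_explained
    if trends is not None:
        summary["trend_slope_n_per_yr"] = trends.slope
        summary["trend_p_linear"] = trends.p_linear
        summary["trend_logit_coef"] = None if trends.degenerate_logit else trends.logit_coef

    manifest = {"config": {k: v for k, v in cfg.items() if k != "schedule"},
                "config_hash": config_hash(cfg), "seed": seed, "summary": summary}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    return summary
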
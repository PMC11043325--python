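"""End-to-end orchestration: clean -> classify -> fit -> standardize ->
impute -> scale up -> ensemble -> production -> validate.

Inputs come either from user-supplied CSV/GeoJSON paths or, when paths are
absent, from the synthetic generator (seeded by the pipeline seed), so the
whole pipeline runs reproducibly with no external data. Every run produces
a report mirroring the schema-by-region totals table with its ensemble mean
and SE, a production line, a validation block, and a manifest (config hash,
seed, per-stage row counts) sufficient to re-run identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import simulate
from .classify import assign_schema
from .config import PipelineConfig, SimulationConfig, config_hash
from .gamm import EstimationError, FishDensityGAMM, ModelSpec, prepare_model_table
from .inventory import (approximate_missing_area, assign_ecoregion,
                        clean_inventory, load_ecoregions, load_inventory)
from .scale_up import (aggregate_stock, build_stock_table,
                       ensemble_across_schemas, impute_densities,
                       production_from_biomass)
from .surveys import link_surveys, load_surveys
from .validate import fit_mixed_calibration

_STAGES = ("simulate", "clean", "classify", "fit", "scaleup", "validate",
           "report")


class PipelineError(RuntimeError):
    """A stage failed; .stage names where."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _stage_guard(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def run_pipeline(config: PipelineConfig, until: str = "report",
                 write: bool = False) -> dict:
    """Execute the pipeline and return an artifacts dict.

    ``until`` stops after a named stage (simulate/clean/classify/fit/
    scaleup/validate/report). With ``write=True`` tables, the JSON report
    and the manifest are written under ``config.output_dir``.
    """
    if until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}")
    stop = _STAGES.index(until)
    art: dict = {"config": config}
    counts: dict[str, int] = {}

    # ---- inputs ------------------------------------------------------
    sim_cfg = config.simulation or SimulationConfig(seed=config.seed)
    simulate_needed = config.inventory_path is None \
        or config.surveys_path is None
    if config.inventory_path is None:
        inv = _stage_guard("simulate", simulate.simulate_inventory, sim_cfg)
        truth, truth_total = simulate.true_summary(
            inv, sim_cfg, year=config.standardization_year)
        art["truth"], art["truth_total_kg"] = truth, truth_total
    else:
        inv, warn = _stage_guard("inventory", load_inventory,
                                 config.inventory_path)
        art["inventory_warnings"] = warn
    counts["inventory_rows"] = len(inv)
    art["inventory_raw"] = inv
    if stop == 0:
        return art

    # ---- clean -------------------------------------------------------
    cleaned, clean_report = _stage_guard(
        "clean", clean_inventory, inv, config.natural_lake_names)
    cleaned, area_report = _stage_guard("clean", approximate_missing_area,
                                        cleaned)
    if config.ecoregions_path is not None:
        polys = _stage_guard("clean", load_ecoregions, config.ecoregions_path)
    else:
        polys = simulate.ecoregion_polygons(sim_cfg)
    cleaned, eco_report = _stage_guard("clean", assign_ecoregion, cleaned,
                                       polys)
    art.update(cleaned_inventory=cleaned, clean_report=clean_report,
               area_report=area_report, ecoregion_report=eco_report)
    counts["cleaned_rows"] = len(cleaned)
    if stop == 1:
        return art

    # ---- classify ----------------------------------------------------
    assignments = {}
    for s in config.schemas:
        assignments[s] = _stage_guard("classify", assign_schema, cleaned, s,
                                      config.seed, config.k_clusters)
    art["assignments"] = assignments
    if stop == 2:
        return art

    # ---- surveys + fit ----------------------------------------------
    if config.surveys_path is None:
        if config.inventory_path is not None:
            # real inventory without survey data: nothing to fit
            raise PipelineError("surveys", "no surveys path configured")
        def _sim_surveys():
            if len(inv) == 0:
                raise ValueError("empty inventory")
            return simulate.simulate_surveys(inv, sim_cfg)
        surveys_df, skipped = _stage_guard("surveys", _sim_surveys)
        art["n_skipped_survey_draws"] = skipped
    else:
        surveys_df, warn = _stage_guard("surveys", load_surveys,
                                        config.surveys_path,
                                        year_range=config.plausible_year_range)
        art["survey_warnings"] = warn
    linked, unmatched = _stage_guard("surveys", link_surveys, surveys_df,
                                     cleaned, config.recovery_constant)
    counts["surveys_linked"] = len(linked)
    counts["surveys_unmatched"] = len(unmatched)
    art.update(linked_surveys=linked, unmatched_surveys=unmatched)

    sy = config.standardization_year
    fits, prep_reports = {}, {}
    for s in config.schemas:
        spec = ModelSpec(basis_dim=config.basis_dim,
                         min_class_n=config.min_class_n,
                         standardization_year=sy)
        def _fit_one(s=s, spec=spec):
            table, rep = prepare_model_table(linked, assignments[s], spec)
            prep_reports[s] = rep
            return FishDensityGAMM(table, spec).fit()
        fits[s] = _stage_guard("fit", _fit_one)
    art.update(fits=fits, model_prep_reports=prep_reports)
    if stop == 3:
        return art

    # ---- impute + scale up ------------------------------------------
    stock_tables, region_totals = {}, {}
    for s in config.schemas:
        def _scale_one(s=s):
            fit = fits[s]
            class_means = fit.class_mean_density(sy)
            global_mean = fit.global_mean_density(sy)
            dens = impute_densities(cleaned, assignments[s], class_means,
                                    global_mean, fit=fit, year=sy)
            return build_stock_table(dens, s)
        stock_tables[s] = _stage_guard("scaleup", _scale_one)
        reg = aggregate_stock(stock_tables[s], "region",
                              config.southern_states)
        region_totals[s] = dict(zip(reg["group"], reg["standing_stock_kg"]))
    art["stock_tables"] = stock_tables
    art["region_totals"] = region_totals

    ensembles = {}
    if len(config.schemas) >= 2:
        for region in ("southern", "USA"):
            ensembles[region] = ensemble_across_schemas(
                {s: region_totals[s][region] for s in config.schemas})
    art["ensembles"] = ensembles

    production = {}
    for region in ("southern", "USA"):
        totals = {s: region_totals[s][region] for s in config.schemas}
        biomass = ensembles[region].mean if region in ensembles \
            else float(np.mean(list(totals.values())))
        point = production_from_biomass(biomass, config.pb_mean,
                                        config.pb_q25, config.pb_q75)
        production[region] = {
            "biomass_kg": biomass,
            "production_kg_y": point.production_kg_y,
            "production_iqr_kg_y": [point.iqr_low_kg_y, point.iqr_high_kg_y],
            "production_range_kg_y": [min(totals.values()) * config.pb_mean,
                                      max(totals.values()) * config.pb_mean],
        }
    art["production"] = production
    if stop == 4:
        return art

    # ---- validation --------------------------------------------------
    calibration = None
    if config.validation_path is not None:
        val = _stage_guard("validate", pd.read_csv, config.validation_path)
    elif simulate_needed and config.inventory_path is None:
        val = simulate.simulate_validation(inv, sim_cfg, year=sy)
    else:
        val = pd.DataFrame(columns=["reservoir_id", "observed_kg"])
    if len(val) >= 3:
        def _calibrate():
            obs, pred, grp = [], [], []
            for s in config.schemas:
                stock = stock_tables[s].set_index("reservoir_id")
                found = val[val["reservoir_id"].isin(stock.index)]
                obs.extend(found["observed_kg"].tolist())
                pred.extend(stock.loc[found["reservoir_id"],
                                      "standing_stock_kg"].tolist())
                grp.extend([f"schema{s}"] * len(found))
            if len(obs) < 3:
                return None
            return fit_mixed_calibration(obs, pred, grp)
        calibration = _stage_guard("validate", _calibrate)
    art["calibration"] = calibration
    counts["validation_pairs"] = len(val)
    if stop == 5:
        return art

    # ---- report ------------------------------------------------------
    report = {
        "totals_by_schema": {str(s): {r: float(region_totals[s][r])
                                      for r in ("southern", "USA")}
                             for s in config.schemas},
        "ensemble": {r: {"mean_kg": e.mean, "se_kg": e.se, "n_schemas": e.n}
                     for r, e in ensembles.items()},
        "production": production,
        "validation": calibration.to_dict() if calibration is not None
        else None,
        "manifest": {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "row_counts": counts,
        },
    }
    if art.get("truth_total_kg") is not None:
        report["synthetic_truth_total_kg"] = float(art["truth_total_kg"])
    art["report"] = report

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, tab in stock_tables.items():
            tab.to_csv(out / f"stock_schema{s}.csv", index=False,
                       float_format="%.10g")
        ens_rows = [{"region": r, "mean_kg": e.mean, "se_kg": e.se}
                    for r, e in ensembles.items()]
        pd.DataFrame(ens_rows).to_csv(out / "ensemble.csv", index=False,
                                      float_format="%.10g")
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=float))
        (out / "manifest.json").write_text(
            json.dumps(report["manifest"], indent=2, sort_keys=True))
    return art
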
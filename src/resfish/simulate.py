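"""Synthetic dam-inventory, rotenone-survey, and validation generators.

The generator draws a national-scale reservoir inventory (jointly log-normal
volume and discharge with ecoregion structure and four latent size-flow
classes), survey densities from a class-specific age response plus year trend,
per-reservoir random intercept and Gamma noise, and an independent validation
set. It also produces the exact ground-truth standing-stock table used by
parameter-recovery tests.

Columns prefixed with an underscore are generator ground truth; the CSV
writers drop them so the written tables look like field data.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping

from .config import NATURAL_LAKE_NAMES, SOUTHERN_STATES, SimulationConfig

_STATES_EXTRA = ("CA", "CO", "OH", "MI", "MN", "NE", "PA", "NY")
# sign pattern (volume, discharge) of the four latent size-flow classes
_CLASS_SIGNS = np.array([(-1, -1), (-1, 1), (1, -1), (1, 1)], dtype=float)


def _streams(config: SimulationConfig):
    """Independent child RNG streams so tables do not perturb each other."""
    inv_ss, surv_ss, val_ss = np.random.SeedSequence(config.seed).spawn(3)
    return (np.random.default_rng(inv_ss), np.random.default_rng(surv_ss),
            np.random.default_rng(val_ss))


def ecoregion_polygons(config: SimulationConfig) -> list[tuple[str, Polygon]]:
    """Square-ish tiling of the bounding box, one strip per ecoregion."""
    x0, y0, x1, y1 = config.bbox
    edges = np.linspace(x0, x1, config.n_ecoregions + 1)
    polys = []
    for i in range(config.n_ecoregions):
        poly = Polygon([(edges[i], y0), (edges[i + 1], y0),
                        (edges[i + 1], y1), (edges[i], y1)])
        polys.append((f"E{i + 1}", poly))
    return polys


def _age_curve(age: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Transient post-impoundment response on the log-density scale."""
    return config.age_curve_alpha * age * np.exp(-age / config.age_curve_tau)


def _log_mean_density(cls, age, year, u, config: SimulationConfig):
    beta0 = np.asarray(config.density_intercept_per_class)[cls]
    return (beta0 + _age_curve(np.asarray(age, dtype=float), config)
            + config.year_trend_slope * (np.asarray(year, dtype=float)
                                         - config.year_range[0]) + u)


def simulate_inventory(config: SimulationConfig) -> pd.DataFrame:
    """Draw the reservoir inventory table.

    Includes injected duplicate-dam rows and flagged natural-lake rows for
    the cleaner, and MCAR missingness in area, coordinates and discharge.
    """
    rng, _, _ = _streams(config)
    n = config.n_reservoirs
    cols = ["reservoir_id", "name", "state", "latitude", "longitude",
            "year_completed", "storage_volume_m3", "max_discharge_m3s",
            "surface_area_ha", "natural_lake",
            "_true_class", "_u", "_area_true", "_ecoregion_true",
            "_is_duplicate"]
    if n == 0:
        return pd.DataFrame(columns=cols)

    x0, y0, x1, y1 = config.bbox
    lon = rng.uniform(x0, x1, n)
    lat = rng.uniform(y0, y1, n)
    edges = np.linspace(x0, x1, config.n_ecoregions + 1)
    eco_idx = np.clip(np.searchsorted(edges, lon, side="right") - 1,
                      0, config.n_ecoregions - 1)
    eco = np.array([f"E{i + 1}" for i in eco_idx])
    eco_shift = rng.normal(0.0, config.ecoregion_volume_shift_sd,
                           config.n_ecoregions)

    cls = rng.integers(0, len(config.density_intercept_per_class), n)
    signs = _CLASS_SIGNS[np.minimum(cls, 3)]
    sv, sq = config.ln_volume_sd, config.ln_discharge_sd
    rho = config.volume_discharge_corr
    cov = np.array([[sv**2, rho * sv * sq], [rho * sv * sq, sq**2]])
    # svd method tolerates the semidefinite edge cases (sd = 0, |rho| = 1)
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="svd")
    ln_vol = (config.ln_volume_mean + eco_shift[eco_idx]
              + config.class_separation * sv * signs[:, 0] + z[:, 0])
    ln_dis = (config.ln_discharge_mean
              + config.class_separation * sq * signs[:, 1] + z[:, 1])
    volume = np.exp(ln_vol)
    discharge = np.exp(ln_dis)
    area = (config.area_coeff * volume**config.area_exponent
            * np.exp(rng.normal(0.0, config.area_noise_sd, n)))

    state_pool = np.array(sorted(set(_STATES_EXTRA) | set(SOUTHERN_STATES)))
    state = rng.choice(state_pool, n)
    year_completed = rng.integers(config.completion_year_range[0],
                                  config.completion_year_range[1] + 1, n)
    u = rng.normal(0.0, config.random_intercept_sd, n)

    df = pd.DataFrame({
        "reservoir_id": [f"R{i:06d}" for i in range(n)],
        "name": [f"Reservoir {i:06d}" for i in range(n)],
        "state": state,
        "latitude": lat,
        "longitude": lon,
        "year_completed": year_completed,
        "storage_volume_m3": volume,
        "max_discharge_m3s": discharge,
        "surface_area_ha": area,
        "natural_lake": False,
        "_true_class": cls,
        "_u": u,
        "_area_true": area.copy(),
        "_ecoregion_true": eco,
        "_is_duplicate": False,
    })

    # MCAR missingness (base rows only)
    for col, frac in (("surface_area_ha", config.missing_area_fraction),
                      ("max_discharge_m3s", config.missing_discharge_fraction)):
        if frac > 0:
            miss = rng.random(n) < frac
            df.loc[miss, col] = np.nan
    if config.missing_coord_fraction > 0:
        miss = rng.random(n) < config.missing_coord_fraction
        df.loc[miss, ["latitude", "longitude"]] = np.nan

    # duplicate-dam rows: same reservoir listed under a second, smaller dam
    n_dup = int(round(config.duplicate_fraction * n))
    if n_dup > 0:
        idx = rng.choice(n, size=min(n_dup, n), replace=False)
        dup = df.iloc[idx].copy()
        dup["reservoir_id"] = [f"D{i:06d}" for i in range(len(dup))]
        dup["storage_volume_m3"] = dup["storage_volume_m3"].to_numpy() * rng.uniform(0.1, 0.5, len(dup))
        dup["_is_duplicate"] = True
        df = pd.concat([df, dup], ignore_index=True)

    # flagged natural-lake rows (large waterbodies with small dams)
    if config.n_natural_lakes > 0:
        names = [NATURAL_LAKE_NAMES[i % len(NATURAL_LAKE_NAMES)]
                 for i in range(config.n_natural_lakes)]
        lakes = pd.DataFrame({
            "reservoir_id": [f"L{i:03d}" for i in range(len(names))],
            "name": names,
            "state": rng.choice(state_pool, len(names)),
            "latitude": rng.uniform(y0, y1, len(names)),
            "longitude": rng.uniform(x0, x1, len(names)),
            "year_completed": rng.integers(1900, 1950, len(names)),
            "storage_volume_m3": rng.uniform(1e11, 1e13, len(names)),
            "max_discharge_m3s": rng.uniform(1e3, 1e4, len(names)),
            "surface_area_ha": rng.uniform(1e5, 8e6, len(names)),
            "natural_lake": True,
            "_true_class": -1,
            "_u": 0.0,
            "_area_true": 0.0,
            "_ecoregion_true": "E1",
            "_is_duplicate": False,
        })
        df = pd.concat([df, lakes], ignore_index=True)
    return df


def _eligible(inventory: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    ok = (~inventory["natural_lake"]) & (~inventory["_is_duplicate"]) \
        & (inventory["year_completed"] <= config.year_range[1])
    return inventory[ok]


def simulate_surveys(inventory: pd.DataFrame,
                     config: SimulationConfig) -> tuple[pd.DataFrame, int]:
    """Draw the rotenone survey table.

    Returns (surveys, n_skipped) where n_skipped counts draws discarded
    because the sampled year preceded reservoir completion.
    """
    cols = ["survey_id", "reservoir_id", "year_sampled", "raw_density_kg_ha"]
    if config.survey_fraction == 0:
        return pd.DataFrame(columns=cols), 0
    if len(inventory) == 0:
        raise ValueError("cannot sample surveys from an empty inventory")
    _, rng, _ = _streams(config)
    pool = _eligible(inventory, config)
    n_sampled = min(len(pool), int(round(config.survey_fraction * len(pool))))
    chosen = pool.iloc[rng.choice(len(pool), size=n_sampled, replace=False)]

    rows = []
    skipped = 0
    lo, hi = config.year_range
    for _, res in chosen.iterrows():
        years = rng.integers(lo, hi + 1, config.surveys_per_reservoir)
        eps = (np.ones(len(years)) if config.expectation_mode
               else rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape,
                              len(years)))
        for year, e in zip(years, eps):
            if year < res["year_completed"]:
                skipped += 1
                continue
            age = year - res["year_completed"]
            mu = math.exp(_log_mean_density(int(res["_true_class"]), age,
                                            year, res["_u"], config))
            rows.append((res["reservoir_id"], int(year), mu * e))
    df = pd.DataFrame(rows, columns=["reservoir_id", "year_sampled",
                                     "true_density"])
    df.insert(0, "survey_id", [f"S{i:06d}" for i in range(len(df))])
    df["raw_density_kg_ha"] = df.pop("true_density") / config.recovery_constant
    return df, skipped


def true_summary(inventory: pd.DataFrame, config: SimulationConfig,
                 year: int = 1993) -> tuple[pd.DataFrame, float]:
    """Exact expected density and standing stock at the standardization year.

    Uses the generator's latent class, random intercept and true surface
    area; excludes duplicate-dam and natural-lake rows (the cleaner removes
    them). Expectation of the Gamma noise term is 1.
    """
    if len(inventory) == 0:
        return pd.DataFrame(columns=["reservoir_id", "true_class",
                                     "density_1993", "area_ha",
                                     "standing_stock_kg"]), 0.0
    base = inventory[(~inventory["natural_lake"])
                     & (~inventory["_is_duplicate"])]
    age = (year - base["year_completed"]).clip(lower=0).to_numpy(dtype=float)
    dens = np.exp(_log_mean_density(base["_true_class"].to_numpy(), age,
                                    np.full(len(base), year, dtype=float),
                                    base["_u"].to_numpy(), config))
    out = pd.DataFrame({
        "reservoir_id": base["reservoir_id"].to_numpy(),
        "true_class": base["_true_class"].to_numpy(),
        "density_1993": dens,
        "area_ha": base["_area_true"].to_numpy(),
        "standing_stock_kg": dens * base["_area_true"].to_numpy(),
    })
    return out, float(out["standing_stock_kg"].sum())


def simulate_validation(inventory: pd.DataFrame, config: SimulationConfig,
                        year: int = 1993) -> pd.DataFrame:
    """Independent whole-reservoir survey stocks: truth times log-normal noise."""
    truth, _ = true_summary(inventory, config, year=year)
    if len(truth) == 0 or config.n_validation == 0:
        return pd.DataFrame(columns=["reservoir_id", "observed_kg"])
    _, _, rng = _streams(config)
    n = min(config.n_validation, len(truth))
    pick = truth.iloc[rng.choice(len(truth), size=n, replace=False)]
    noise = np.exp(rng.normal(0.0, config.validation_noise_sd, n))
    return pd.DataFrame({"reservoir_id": pick["reservoir_id"].to_numpy(),
                         "observed_kg": pick["standing_stock_kg"].to_numpy()
                         * noise})


# ---------------------------------------------------------------- writers

_FLOAT_FMT = "%.10g"


def _public(df: pd.DataFrame) -> pd.DataFrame:
    return df[[c for c in df.columns if not c.startswith("_")]]


def write_inventory(df: pd.DataFrame, path: str | Path) -> None:
    _public(df).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    _public(df).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_validation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_truth(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_ecoregions_geojson(config: SimulationConfig, path: str | Path) -> None:
    features = [{"type": "Feature",
                 "properties": {"ecoregion_l2": label},
                 "geometry": mapping(poly)}
                for label, poly in ecoregion_polygons(config)]
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, sort_keys=True))


def write_all(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate and write every synthetic table; returns the tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = simulate_inventory(config)
    surveys, skipped = simulate_surveys(inventory, config) \
        if config.survey_fraction > 0 and len(inventory) else \
        (pd.DataFrame(columns=["survey_id", "reservoir_id", "year_sampled",
                               "raw_density_kg_ha"]), 0)
    truth, total = true_summary(inventory, config)
    validation = simulate_validation(inventory, config)
    write_inventory(inventory, out / "inventory.csv")
    write_surveys(surveys, out / "surveys.csv")
    write_truth(truth, out / "truth.csv")
    write_validation(validation, out / "validation.csv")
    write_ecoregions_geojson(config, out / "ecoregions.geojson")
    from .config import save_config
    save_config(config, out / "simulation_config.yml")
    return {"inventory": inventory, "surveys": surveys, "truth": truth,
            "validation": validation, "total_kg": total,
            "n_skipped_surveys": skipped}
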
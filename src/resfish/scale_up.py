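"""Areal scale-up: impute densities, compute standing stock, aggregate,
ensemble across classification schemas, and convert biomass to production.

Every reservoir in the cleaned inventory receives a density for the
standardization year: its own model prediction if it was surveyed, the
class-specific mean if its class was surveyed, otherwise the mean over all
sampled reservoirs. Standing stock is density times surface area; regional
totals are plain sums; the ensemble mean and SE across the five schema
totals is the uncertainty statement "across calculations"; production is
biomass times a literature whole-community P/B ratio with an interquartile
range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import UNCLASSIFIED

UNASSIGNED = "unassigned"


def impute_densities(inventory: pd.DataFrame, assignments: pd.DataFrame,
                     class_means: dict[str, float], global_mean: float,
                     fit=None, year: float | None = None) -> pd.DataFrame:
    """Assign a standardized density (kg/ha) to every reservoir.

    Provenance flags: "model" (sampled reservoir, own prediction),
    "class_mean", "global_mean".
    """
    df = inventory.merge(assignments[["reservoir_id", "class_label"]],
                         on="reservoir_id", how="left")
    dens = np.empty(len(df))
    prov = np.empty(len(df), dtype=object)
    sampled = set(fit.model.class_of_reservoir) if fit is not None else set()
    for i, row in enumerate(df.itertuples(index=False)):
        rid = row.reservoir_id
        label = row.class_label
        if fit is not None and rid in sampled:
            dens[i] = fit.predict(fit.model.class_of_reservoir[rid],
                                  year if year is not None
                                  else fit.model.spec.standardization_year,
                                  reservoir_id=rid)
            prov[i] = "model"
        elif label is not None and not pd.isna(label) \
                and label != UNCLASSIFIED and label in class_means:
            dens[i] = class_means[label]
            prov[i] = "class_mean"
        else:
            dens[i] = global_mean
            prov[i] = "global_mean"
    out = df[["reservoir_id", "class_label", "state",
              "surface_area_ha"]].copy()
    if "ecoregion_l2" in df.columns:
        out["ecoregion_l2"] = df["ecoregion_l2"]
    out["density_kg_ha"] = dens
    out["imputed"] = prov
    return out


def standing_stock(density, area):
    """Standing stock (kg) = density (kg/ha) x surface area (ha)."""
    d = np.asarray(density, dtype=float)
    a = np.asarray(area, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be >= 0")
    if np.any(~np.isnan(a) & (a <= 0)):
        raise ValueError("surface area must be > 0")
    out = d * a
    return float(out) if np.isscalar(density) and np.isscalar(area) else out


def build_stock_table(densities: pd.DataFrame, schema_id: int) -> pd.DataFrame:
    """Per-reservoir stock rows for one schema."""
    df = densities.copy()
    df["standing_stock_kg"] = standing_stock(
        df["density_kg_ha"].to_numpy(), df["surface_area_ha"].to_numpy())
    df.insert(1, "schema_id", schema_id)
    return df


def aggregate_stock(stock: pd.DataFrame, by: str = "national",
                    southern_states: tuple[str, ...] = ()) -> pd.DataFrame:
    """Group sums of standing stock.

    ``by`` is one of national, state, ecoregion, region (southern vs USA).
    Missing state/ecoregion rows aggregate into an explicit "unassigned"
    bucket so group totals always partition the national total.
    """
    df = stock
    if by == "national":
        return pd.DataFrame({"group": ["USA"],
                             "standing_stock_kg":
                             [df["standing_stock_kg"].sum()]})
    if by == "state":
        key = df["state"].fillna(UNASSIGNED)
    elif by == "ecoregion":
        key = df.get("ecoregion_l2",
                     pd.Series(np.nan, index=df.index)).fillna(UNASSIGNED)
    elif by == "region":
        southern = df["state"].isin(southern_states)
        out = pd.DataFrame({
            "group": ["southern", "USA"],
            "standing_stock_kg": [df.loc[southern, "standing_stock_kg"].sum(),
                                  df["standing_stock_kg"].sum()]})
        return out
    else:
        raise ValueError(f"unknown grouping {by!r}")
    agg = df.groupby(key.rename("group"))["standing_stock_kg"].sum()
    return agg.reset_index()


@dataclass
class EnsembleSummary:
    """Mean and SE of regional totals across classification schemas."""

    totals: dict[int, float]
    mean: float
    se: float

    @property
    def n(self) -> int:
        return len(self.totals)


def ensemble_across_schemas(totals: dict[int, float]) -> EnsembleSummary:
    """Mean and sd/sqrt(n) across the schema totals (sample sd, n-1)."""
    if len(totals) < 2:
        raise ValueError("ensemble needs at least two schema totals")
    vals = np.array(list(totals.values()), dtype=float)
    return EnsembleSummary(totals=dict(totals), mean=float(vals.mean()),
                           se=float(vals.std(ddof=1) / np.sqrt(len(vals))))


@dataclass
class ProductionEstimate:
    """Secondary production from biomass via a whole-community P/B ratio."""

    production_kg_y: float
    iqr_low_kg_y: float
    iqr_high_kg_y: float
    pb_mean: float
    pb_q25: float
    pb_q75: float


def production_from_biomass(biomass_kg: float, pb_mean: float = 1.30,
                            pb_q25: float = 0.583, pb_q75: float = 1.823
                            ) -> ProductionEstimate:
    """P = B x P/B, with an interquartile range from the P/B quartiles."""
    if biomass_kg < 0:
        raise ValueError("biomass must be >= 0")
    if min(pb_mean, pb_q25, pb_q75) <= 0:
        raise ValueError("P/B parameters must be > 0")
    if pb_q25 > pb_q75:
        raise ValueError("pb_q25 must not exceed pb_q75")
    return ProductionEstimate(
        production_kg_y=biomass_kg * pb_mean,
        iqr_low_kg_y=biomass_kg * pb_q25,
        iqr_high_kg_y=biomass_kg * pb_q75,
        pb_mean=pb_mean, pb_q25=pb_q25, pb_q75=pb_q75)
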
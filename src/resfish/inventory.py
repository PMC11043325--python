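"""Dam/reservoir inventory: loading, cleaning, area approximation, ecoregion join.

Cleaning mirrors the tidying a national dam registry needs before areal
scale-up: reservoirs listed once per dam are collapsed to a single record,
natural lakes impounded by small regulating dams are removed, and records
with no basis for a surface-area estimate are dropped. Every removal is
counted in a report so row counts reconcile exactly.
"""

from __future__ import annotations

import json
import re
import string
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape

from .config import NATURAL_LAKE_NAMES

_CANONICAL = ["reservoir_id", "name", "state", "latitude", "longitude",
              "year_completed", "storage_volume_m3", "max_discharge_m3s",
              "surface_area_ha", "natural_lake"]
_NUMERIC = ["latitude", "longitude", "year_completed", "storage_volume_m3",
            "max_discharge_m3s", "surface_area_ha"]

_PUNCT = re.compile(f"[{re.escape(string.punctuation)}\\s]+")


class SchemaError(ValueError):
    """Input table lacks a mandatory column."""


def normalize_name(name, state=None) -> str:
    """Case-folded, punctuation/whitespace-stripped identity key."""
    key = _PUNCT.sub("", str(name).casefold())
    if state is not None and not pd.isna(state):
        key = f"{key}|{str(state).strip().upper()}"
    return key


def load_inventory(path: str | Path, column_map: dict | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Read an inventory CSV into typed records.

    ``column_map`` maps canonical names (reservoir_id, name, state, latitude,
    longitude, year_completed, storage_volume_m3, max_discharge_m3s,
    surface_area_ha, natural_lake) to the file's column names. Unparseable
    numeric cells become missing; per-column coercion counts are returned as
    warnings.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # keep NA-like tokens ("n/a", "NA", ...) visible so they are counted
    # as coercions rather than silently read as missing
    raw = pd.read_csv(path, keep_default_na=False, na_values=("",))
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items() if v in raw.columns}
    df = raw.rename(columns=rename)
    if "reservoir_id" not in df.columns:
        raise SchemaError("inventory is missing the reservoir_id column")
    for col in _CANONICAL:
        if col not in df.columns:
            df[col] = False if col == "natural_lake" else np.nan
    warnings: dict[str, int] = {}
    for col in _NUMERIC:
        before = df[col].notna()
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = int((before & df[col].isna()).sum())
        if bad:
            warnings[col] = bad
    truthy = {"true", "1", "t", "yes"}
    df["natural_lake"] = df["natural_lake"].map(
        lambda v: str(v).strip().lower() in truthy)
    bad_lat = df["latitude"].notna() & ~df["latitude"].between(-90, 90)
    bad_lon = df["longitude"].notna() & ~df["longitude"].between(-180, 180)
    if bad_lat.any() or bad_lon.any():
        warnings["coordinates_out_of_range"] = int((bad_lat | bad_lon).sum())
        df.loc[bad_lat, "latitude"] = np.nan
        df.loc[bad_lon, "longitude"] = np.nan
    return df[_CANONICAL + [c for c in df.columns if c not in _CANONICAL]], warnings


def clean_inventory(records: pd.DataFrame,
                    natural_lake_names: tuple[str, ...] = NATURAL_LAKE_NAMES
                    ) -> tuple[pd.DataFrame, dict]:
    """Apply the three cleaning rules; always returns (records, report).

    1. natural lakes (flag column or name on the exclusion list) dropped;
    2. rows with neither surface area nor storage volume dropped;
    3. rows sharing an identity key (normalized name + state) collapsed to
       the maximum-storage-volume dam.
    """
    report = {"rows_in": len(records), "natural_lakes": 0,
              "no_area_basis": 0, "duplicates": 0}
    df = records.copy()
    if len(df) == 0:
        report["rows_out"] = 0
        return df, report

    lake_keys = {normalize_name(n) for n in natural_lake_names}
    name_key = df["name"].map(normalize_name)
    is_lake = df.get("natural_lake", pd.Series(False, index=df.index)
                     ).fillna(False).astype(bool) | name_key.isin(lake_keys)
    report["natural_lakes"] = int(is_lake.sum())
    df = df[~is_lake]

    no_basis = df["surface_area_ha"].isna() & df["storage_volume_m3"].isna()
    report["no_area_basis"] = int(no_basis.sum())
    df = df[~no_basis]

    key = df.apply(lambda r: normalize_name(r["name"], r.get("state")), axis=1) \
        if len(df) else pd.Series(dtype=object)
    if len(df):
        # keep the maximum-volume dam per reservoir identity; stable on ties
        order = df.assign(_key=key.to_numpy(),
                          _vol=df["storage_volume_m3"].fillna(-np.inf))
        keep = order.sort_values("_vol", kind="stable").groupby("_key").tail(1)
        report["duplicates"] = len(df) - len(keep)
        df = keep.drop(columns=["_key", "_vol"]).sort_index()

    report["rows_out"] = len(df)
    return df.reset_index(drop=True), report


def approximate_missing_area(records: pd.DataFrame,
                             min_complete: int = 10
                             ) -> tuple[pd.DataFrame, dict]:
    """Fill missing surface areas from storage volume.

    With at least ``min_complete`` complete (area, volume) pairs, predicts
    ln(area) from ln(volume) by OLS and back-transforms; otherwise falls back
    to median(area/volume) scaling. Observed areas are never modified.
    """
    df = records.copy()
    complete = df["surface_area_ha"].notna() & df["storage_volume_m3"].notna() \
        & (df["surface_area_ha"] > 0) & (df["storage_volume_m3"] > 0)
    target = df["surface_area_ha"].isna() & df["storage_volume_m3"].notna() \
        & (df["storage_volume_m3"] > 0)
    info: dict = {"n_complete": int(complete.sum()),
                  "n_approximated": int(target.sum()), "method": None}
    if "area_approximated" not in df.columns:
        df["area_approximated"] = False
    if not target.any():
        return df, info
    if not complete.any():
        raise ValueError("no record has both surface area and storage volume")
    lv = np.log(df.loc[complete, "storage_volume_m3"].to_numpy())
    la = np.log(df.loc[complete, "surface_area_ha"].to_numpy())
    if complete.sum() >= min_complete:
        slope, intercept = np.polyfit(lv, la, 1)
        pred = np.exp(intercept + slope
                      * np.log(df.loc[target, "storage_volume_m3"].to_numpy()))
        info["method"] = "loglog_ols"
        info["slope"], info["intercept"] = float(slope), float(intercept)
    else:
        ratio = float(np.median(np.exp(la - lv)))
        pred = ratio * df.loc[target, "storage_volume_m3"].to_numpy()
        info["method"] = "median_ratio"
        info["ratio"] = ratio
    df.loc[target, "surface_area_ha"] = pred
    df.loc[target, "area_approximated"] = True
    return df, info


def load_ecoregions(path: str | Path, label_key: str = "ecoregion_l2"
                    ) -> list[tuple[str, shapely.Geometry]]:
    """Read an ecoregion polygon layer from GeoJSON (WGS84 lon/lat)."""
    data = json.loads(Path(path).read_text())
    feats = data["features"] if data.get("type") == "FeatureCollection" else [data]
    polys = []
    for feat in feats:
        props = feat.get("properties", {})
        label = props.get(label_key) or next(iter(props.values()), None)
        polys.append((str(label), shape(feat["geometry"])))
    return polys


def assign_ecoregion(records: pd.DataFrame,
                     polygons: list[tuple[str, shapely.Geometry]]
                     ) -> tuple[pd.DataFrame, dict]:
    """Point-in-polygon join of records to ecoregion labels.

    A point on a shared edge goes to the first polygon in layer order
    (covers-semantics, deterministic). Records without coordinates or outside
    every polygon keep a missing ecoregion and are counted.
    """
    if not polygons:
        raise ValueError("empty ecoregion polygon layer")
    df = records.copy()
    df["ecoregion_l2"] = pd.Series(np.nan, index=df.index, dtype=object)
    has_xy = df["latitude"].notna() & df["longitude"].notna()
    pts = shapely.points(df.loc[has_xy, "longitude"].to_numpy(),
                         df.loc[has_xy, "latitude"].to_numpy())
    assigned = np.zeros(len(pts), dtype=bool)
    labels = np.array([None] * len(pts), dtype=object)
    for label, poly in polygons:
        todo = ~assigned
        if not todo.any():
            break
        inside = shapely.covers(poly, pts[todo])
        hit = np.where(todo)[0][inside]
        labels[hit] = label
        assigned[hit] = True
    df.loc[has_xy, "ecoregion_l2"] = labels
    report = {"no_coordinates": int((~has_xy).sum()),
              "outside_all_polygons": int((~assigned).sum())}
    return df, report
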
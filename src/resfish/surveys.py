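"""Rotenone survey records: loading, recovery correction, inventory linkage.

Cove rotenone surveys undercount fish because block nets are imperfect and
not all killed fish are recovered; a multiplicative constant (1.773056, the
mean of published species recovery rates) converts raw to corrected density.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import RECOVERY_CONSTANT
from .inventory import normalize_name

_CANONICAL = ["survey_id", "reservoir_id", "year_sampled", "raw_density_kg_ha"]


def load_surveys(path: str | Path, column_map: dict | None = None,
                 year_range: tuple[int, int] = (1900, 2026)
                 ) -> tuple[pd.DataFrame, dict]:
    """Read a survey CSV into typed records.

    Rows with negative or unparseable density, or an implausible sampling
    year, are dropped row-wise and counted in the warnings dict.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    column_map = column_map or {}
    df = raw.rename(columns={v: k for k, v in column_map.items()
                             if v in raw.columns})
    if "reservoir_id" not in df.columns:
        raise ValueError("surveys are missing the reservoir_id column")
    if "survey_id" not in df.columns:
        df["survey_id"] = [f"S{i:06d}" for i in range(len(df))]
    warnings: dict[str, int] = {}
    for col in ("year_sampled", "raw_density_kg_ha"):
        df[col] = pd.to_numeric(df.get(col), errors="coerce")
    bad_density = df["raw_density_kg_ha"].isna() | (df["raw_density_kg_ha"] < 0)
    bad_year = df["year_sampled"].isna() \
        | ~df["year_sampled"].between(*year_range)
    if bad_density.any():
        warnings["invalid_density"] = int(bad_density.sum())
    if bad_year.any():
        warnings["invalid_year"] = int(bad_year.sum())
    df = df[~(bad_density | bad_year)].reset_index(drop=True)
    df["year_sampled"] = df["year_sampled"].astype(int)
    return df[_CANONICAL + [c for c in df.columns if c not in _CANONICAL]], warnings


def apply_recovery_correction(raw_density, constant: float = RECOVERY_CONSTANT):
    """Correct raw rotenone density (kg/ha) for incomplete recovery.

    Scalar or array; exact multiplication by the constant.
    """
    arr = np.asarray(raw_density, dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw density must be >= 0")
    if constant < 1:
        raise ValueError("recovery constant must be >= 1")
    out = arr * constant
    return float(out) if np.isscalar(raw_density) else out


def link_surveys(surveys: pd.DataFrame, inventory: pd.DataFrame,
                 constant: float = RECOVERY_CONSTANT
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach surveys to cleaned inventory reservoirs.

    Matches on reservoir_id first, then on normalized name + state. Returns
    (linked, unmatched); no survey appears in both. Linked rows carry the
    corrected density and reservoir age at sampling (missing and flagged when
    the survey predates completion or completion year is unknown).
    """
    inv = inventory.set_index("reservoir_id")
    by_name: dict[str, str] = {}
    for rid, row in inv.iterrows():
        by_name.setdefault(normalize_name(row["name"], row.get("state")), rid)

    resolved = surveys["reservoir_id"].astype(str).where(
        surveys["reservoir_id"].astype(str).isin(inv.index), other=np.nan)
    if "name" in surveys.columns:
        need = resolved.isna()
        keys = surveys.loc[need].apply(
            lambda r: normalize_name(r["name"], r.get("state")), axis=1)
        resolved.loc[need] = keys.map(by_name)

    matched = resolved.notna()
    unmatched = surveys[~matched].copy()
    linked = surveys[matched].copy()
    linked["reservoir_id"] = resolved[matched]
    linked["corrected_density_kg_ha"] = apply_recovery_correction(
        linked["raw_density_kg_ha"].to_numpy(), constant)
    yc = inv["year_completed"].reindex(linked["reservoir_id"]).to_numpy()
    age = linked["year_sampled"].to_numpy(dtype=float) - yc
    negative = ~np.isnan(age) & (age < 0)
    age[negative] = np.nan
    linked["reservoir_age"] = age
    linked["age_flag"] = np.where(
        negative, "sampled_before_completion",
        np.where(np.isnan(age), "unknown_completion_year", ""))
    return linked.reset_index(drop=True), unmatched.reset_index(drop=True)
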
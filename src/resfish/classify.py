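"""Reservoir classification schemas.

Five schemas of increasing complexity place every reservoir into a family:

1. simple average (one class);
2. k-means k=2 on ln(volume+1), labels small/large;
3. global k-means k=4 on ln(volume+1) x ln(discharge+1), labels size|flow;
4. ecoregion membership;
5. per-ecoregion k-means k=4 on the two covariates standardized within
   ecoregion, labels ecoregion|size|flow.

Covariates are ln(x+1) transformed and z-scored within the clustering
stratum before Lloyd's algorithm runs. Records missing a needed covariate
receive the reserved label "unclassified" and are later imputed with the
global mean density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

UNCLASSIFIED = "unclassified"


@dataclass
class ClusteringResult:
    """Best-of-restarts Lloyd's k-means solution on standardized coordinates."""

    assignments: np.ndarray
    centroids: np.ndarray
    within_cluster_sse: float
    n_iterations: int
    seed: int


def kmeans_cluster(points: np.ndarray, k: int, seed: int = 0,
                   n_restarts: int = 25) -> ClusteringResult:
    """Run seeded, multi-restart k-means on an (n, d) matrix."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if not np.all(np.isfinite(pts)):
        raise ValueError("k-means requires finite coordinates")
    if len(pts) < k:
        raise ValueError(f"need at least k={k} points, got {len(pts)}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd").fit(pts)
    return ClusteringResult(assignments=km.labels_.astype(int),
                            centroids=km.cluster_centers_,
                            within_cluster_sse=float(km.inertia_),
                            n_iterations=int(km.n_iter_), seed=seed)


def label_clusters(result: ClusteringResult) -> dict[int, str]:
    """Name clusters by centroid position: {small,large} x {low,high}.

    The half of the centroids with lower volume is "small", the rest
    "large"; likewise "low"/"high" on the discharge axis. Ties are broken by
    the other axis then cluster index, so labelling is deterministic even
    with identical centroids. One-dimensional results get size labels only.
    """
    cent = result.centroids
    k = len(cent)
    idx = np.arange(k)

    def _split(axis: int, other: int | None) -> np.ndarray:
        keys = [cent[:, axis]]
        if other is not None:
            keys.append(cent[:, other])
        keys.append(idx)
        order = np.lexsort(tuple(reversed(keys)))
        half = np.zeros(k, dtype=bool)
        half[order[k // 2:]] = True  # upper half of the split
        return half

    if cent.shape[1] == 1:
        large = _split(0, None)
        return {i: ("large" if large[i] else "small") for i in range(k)}
    large = _split(0, 1)
    high = _split(1, 0)
    return {i: f"{'large' if large[i] else 'small'}"
               f"|{'high' if high[i] else 'low'}" for i in range(k)}


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def _cluster_and_label(df: pd.DataFrame, cols: list[str], k: int, seed: int,
                       prefix: str = "") -> pd.Series:
    x = _standardize(np.log1p(df[cols].to_numpy(dtype=float)))
    res = kmeans_cluster(x, k=k, seed=seed)
    names = label_clusters(res)
    return pd.Series([prefix + names[c] for c in res.assignments],
                     index=df.index)


def assign_schema(records: pd.DataFrame, schema_id: int, seed: int = 0,
                  k: int = 4) -> pd.DataFrame:
    """Assign every reservoir a class label under one schema.

    Returns a frame (reservoir_id, schema_id, class_label). Records missing
    a covariate the schema needs are labelled "unclassified".
    """
    if schema_id not in {1, 2, 3, 4, 5}:
        raise ValueError(f"unknown schema {schema_id}")
    df = records
    labels = pd.Series(UNCLASSIFIED, index=df.index, dtype=object)

    if schema_id == 1:
        labels[:] = "all"
    elif schema_id == 2:
        ok = df["storage_volume_m3"].notna()
        if ok.sum() >= 2:
            labels.loc[ok] = _cluster_and_label(df.loc[ok],
                                                ["storage_volume_m3"], 2, seed)
    elif schema_id == 3:
        ok = df["storage_volume_m3"].notna() & df["max_discharge_m3s"].notna()
        if ok.sum() >= k:
            labels.loc[ok] = _cluster_and_label(
                df.loc[ok], ["storage_volume_m3", "max_discharge_m3s"], k, seed)
    elif schema_id == 4:
        ok = df["ecoregion_l2"].notna()
        labels.loc[ok] = df.loc[ok, "ecoregion_l2"].astype(str)
    else:  # schema 5: per-ecoregion size-flow clustering
        if df["ecoregion_l2"].isna().all():
            raise ValueError("schema 5 requires ecoregion assignments")
        ok = df["ecoregion_l2"].notna() & df["storage_volume_m3"].notna() \
            & df["max_discharge_m3s"].notna()
        for eco, sub in df[ok].groupby("ecoregion_l2", sort=True):
            if len(sub) >= k:
                labels.loc[sub.index] = _cluster_and_label(
                    sub, ["storage_volume_m3", "max_discharge_m3s"], k, seed,
                    prefix=f"{eco}|")
            else:
                # stratum too small to split: one family for the ecoregion
                labels.loc[sub.index] = f"{eco}|all"

    return pd.DataFrame({"reservoir_id": df["reservoir_id"].to_numpy(),
                         "schema_id": schema_id,
                         "class_label": labels.to_numpy()})
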
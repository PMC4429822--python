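"""Temporal clustering of chromatin accessibility across stages.

The per-stage accessibility matrix is normalized in three fixed steps:
each sample's maximum window densities are divided by that sample's SPOT
score (a library-quality correction), transformed by log10(density + 1),
and each row is scaled so its maximum equals 10 (all-zero rows stay zero).
Rows are then partitioned by k-means (default k = 12) and each cluster
centroid is labeled E/M/L (argmax stage), C (flat within tolerance), or O
(valley-shaped profile).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

ROW_MAX = 10.0
FLATNESS_TOL = 0.2


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # dhs_id -> cluster index
    centroids: pd.DataFrame  # cluster x stage
    labels: dict  # cluster -> one of E/M/L/O/C
    inertia: float
    seed: int


def normalize(raw: pd.DataFrame, spot: dict | pd.Series) -> pd.DataFrame:
    """SPOT-correct, log-transform and row-scale the raw density matrix.

    Steps, in order: value / sample SPOT score, then log10(value + 1), then
    each row scaled by 10 / rowmax (rows with all zeros left at zero).
    """
    spot = pd.Series(spot)
    missing = [c for c in raw.columns if c not in spot.index]
    if missing:
        raise ValueError(f"missing SPOT scores for {missing}")
    if (spot.loc[list(raw.columns)] <= 0).any() or (spot.loc[list(raw.columns)] > 1).any():
        raise ValueError("SPOT scores must lie in (0, 1]")
    v = raw.to_numpy(dtype=float) / spot.loc[list(raw.columns)].to_numpy()
    v = np.log10(v + 1.0)
    rowmax = v.max(axis=1)
    safe = np.where(rowmax > 0, rowmax, 1.0)
    # divide first so the row maximum maps to exactly ROW_MAX
    out = (v / safe[:, None]) * ROW_MAX
    out[rowmax <= 0] = 0.0
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def kmeans_cluster(
    matrix: pd.DataFrame, k: int = 12, seed: int = 0, n_init: int = 25
) -> ClusterModel:
    """Lloyd k-means on the transformed matrix (Euclidean distance,
    k-means++ seeding, best of n_init initializations)."""
    if k > len(matrix):
        raise ValueError("k exceeds the number of rows")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=seed % (2**31),
    )
    assign = km.fit_predict(matrix.to_numpy(dtype=float))
    centroids = pd.DataFrame(km.cluster_centers_, columns=matrix.columns)
    labels = label_clusters(centroids, list(matrix.columns))
    return ClusterModel(
        k=k,
        assignments=pd.Series(assign, index=matrix.index, name="cluster"),
        centroids=centroids,
        labels=labels,
        inertia=float(km.inertia_),
        seed=seed,
    )


def label_cluster_profile(c: np.ndarray, flatness_tol: float = FLATNESS_TOL) -> str:
    """Label one centroid profile over ordered stages.

    C if (max-min)/max <= flatness_tol; O if the profile has an interior
    strict minimum below both ends (valley); else E/M/L by argmax stage.
    """
    c = np.asarray(c, dtype=float)
    cmax = c.max()
    if cmax <= 0 or (cmax - c.min()) / cmax <= flatness_tol:
        return "C"
    interior = c[1:-1]
    if len(interior) and interior.min() < c[0] and interior.min() < c[-1]:
        if int(np.argmin(c)) not in (0, len(c) - 1):
            return "O"
    j = int(np.argmax(c))
    if j == 0:
        return "E"
    if j == len(c) - 1:
        return "L"
    return "M"


def label_clusters(centroids: pd.DataFrame, stages: list, flatness_tol: float = FLATNESS_TOL) -> dict:
    if len(stages) < 2:
        raise ValueError("need at least two ordered stages")
    return {
        int(i): label_cluster_profile(centroids.loc[i, stages].to_numpy(), flatness_tol)
        for i in centroids.index
    }


def cluster_summary(
    model: ClusterModel,
    matrix: pd.DataFrame,
    promoter_flags: pd.Series,
    occupancy_by_factor: dict | None = None,
) -> pd.DataFrame:
    """Per-cluster table: size, median transformed accessibility per stage,
    % promoter DHSs, and per ChIP factor the share of that factor's total
    binding sites whose occupied DHS lies in the cluster.

    occupancy_by_factor maps factor -> (per_peak DataFrame with a dhs_id
    column for occupying peaks, total_sites int).
    """
    unknown = set(promoter_flags.index) - set(model.assignments.index)
    if unknown:
        raise ValueError(f"promoter flags reference unknown DHS ids: {sorted(unknown)[:5]}")
    rows = []
    for cl in range(model.k):
        ids = model.assignments.index[model.assignments == cl]
        med = matrix.loc[ids].median(axis=0)
        row = {
            "cluster": cl,
            "label": model.labels[cl],
            "n_dhs": len(ids),
            "pct_promoter": 100.0 * promoter_flags.reindex(ids).fillna(False).mean()
            if len(ids)
            else 0.0,
        }
        for stage in matrix.columns:
            row[f"median_{stage}"] = float(med[stage])
        if occupancy_by_factor:
            idset = set(ids)
            for factor, (per_peak, total_sites) in occupancy_by_factor.items():
                occ = per_peak[per_peak["dhs_id"] != ""]
                n_in = int(occ["dhs_id"].isin(idset).sum())
                row[f"pct_{factor}_sites"] = 100.0 * n_in / max(total_sites, 1)
        rows.append(row)
    return pd.DataFrame(rows)
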
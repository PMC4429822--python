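"""Per-cluster transcription-factor motif enrichment.

A DHS is flagged for a TF when at least one motif hit linked to that TF
(any of the TF's motif models; presence is the union over models) with
match p-value below the scan threshold (default 1e-4) overlaps the DHS.
Enrichment of a TF within a cluster against the master-list background is
the cumulative (upper-tail, inclusive) hypergeometric probability, with
Bonferroni correction over all TF x cluster tests in a run.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .util import overlap_stats, sort_intervals

MATCH_P_THRESHOLD = 1e-4
ALPHA = 0.01
P_FLOOR = 1e-300


def read_fimo(path) -> pd.DataFrame:
    """Read a FIMO-style TSV (motif_id, sequence_name, start, stop, strand,
    score, p-value); 1-based inclusive coordinates become 0-based half-open."""
    from .util import read_tsv

    df = read_tsv(path)
    cols = {c.lower().replace("-", "_"): c for c in df.columns}
    out = pd.DataFrame(
        {
            "motif_id": df[cols["motif_id"]],
            "chrom": df[cols.get("sequence_name", cols.get("chrom"))],
            "start": df[cols["start"]].astype(int) - 1,
            "end": df[cols["stop"]].astype(int),
            "strand": df[cols["strand"]] if "strand" in cols else "+",
            "p_value": df[cols["p_value"]].astype(float),
        }
    )
    if "tf" in cols:
        out["tf"] = df[cols["tf"]]
    return out


def dhs_motif_presence(
    master: pd.DataFrame, hits: pd.DataFrame, p_threshold: float = MATCH_P_THRESHOLD
):
    """Boolean DHS x TF presence table from a motif hit table.

    A DHS is flagged for a TF iff >= 1 hit of any motif linked to that TF
    with match_p < p_threshold overlaps the DHS by >= 1 bp. Hits without a
    TF link are skipped and counted. Returns (presence DataFrame, n_skipped).
    """
    if "tf" in hits.columns:
        linked = hits[hits["tf"].notna() & (hits["tf"] != "")]
    else:
        linked = hits.iloc[0:0]
    n_skipped = len(hits) - len(linked)
    if n_skipped:
        warnings.warn(f"{n_skipped} motif hits had no TF link; skipped", stacklevel=2)
    linked = linked[linked["p_value"] < p_threshold]
    tfs = sorted(linked["tf"].unique()) if len(linked) else []
    presence = pd.DataFrame(False, index=master["dhs_id"].to_numpy(), columns=tfs)
    if not tfs:
        return presence, n_skipped
    dhs_ids = master["dhs_id"].to_numpy()
    for tf, grp in linked.groupby("tf"):
        q = sort_intervals(grp[["chrom", "start", "end"]])
        n_hits, _, best = overlap_stats(q, master)
        hit_rows = best[n_hits > 0]
        presence.loc[np.unique(dhs_ids[hit_rows]), tf] = True
    return presence, n_skipped


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Inclusive upper-tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if K == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    cluster_ids, presence: pd.DataFrame, background_ids=None, cluster_label: str = "cluster"
) -> pd.DataFrame:
    """Per-TF enrichment of motif presence in a cluster vs the background.

    cluster_ids must be a subset of background_ids (default: all presence
    rows). Returns records (tf, cluster, k, n, K, N, p, degenerate).
    """
    if background_ids is None:
        background_ids = presence.index
    background_ids = pd.Index(background_ids)
    cluster_ids = pd.Index(cluster_ids)
    if not cluster_ids.isin(background_ids).all():
        raise ValueError("cluster ids must be a subset of the background")
    sub_bg = presence.loc[background_ids]
    sub_cl = presence.loc[cluster_ids]
    N = len(background_ids)
    n = len(cluster_ids)
    rows = []
    for tf in presence.columns:
        K = int(sub_bg[tf].sum())
        k = int(sub_cl[tf].sum())
        degenerate = K == 0
        if degenerate:
            warnings.warn(f"{tf}: no background presence; p = 1 (degenerate)", stacklevel=2)
        p = hypergeom_pvalue(k, n, K, N)
        rows.append((tf, cluster_label, k, n, K, N, p, degenerate))
    return pd.DataFrame(
        rows, columns=["tf", "cluster", "k", "n", "K", "N", "p", "degenerate"]
    )


def bonferroni(records: pd.DataFrame, m: int | None = None, alpha: float = ALPHA) -> pd.DataFrame:
    """Bonferroni correction over the family of all tests in `records`
    (or an explicit family size m); significance at p_bonf < alpha."""
    out = records.copy()
    m = len(records) if m is None else m
    if m < len(records):
        raise ValueError("family size m smaller than the number of records")
    out["p_bonf"] = np.minimum(1.0, out["p"] * m)
    out["significant"] = out["p_bonf"] < alpha
    return out


def enrichment_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """TF x cluster matrix of -log10 p (degenerate or missing cells are 0)."""
    rec = records.copy()
    rec.loc[rec["degenerate"].astype(bool), "p"] = 1.0
    rec["neglog10p"] = -np.log10(np.maximum(rec["p"].astype(float), P_FLOOR))
    mat = rec.pivot_table(index="tf", columns="cluster", values="neglog10p", fill_value=0.0)
    return mat
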
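"""Cross-sample DHS master list and interval-classification analyses.

The master list is the non-redundant, non-overlapping union of per-sample
DHS peak sets: transitively overlapping peaks are merged and each master
interval is the union span of its contributors. On top of it sit the
classification rules used throughout the analysis: strand-aware 1-kb
promoter assignment, genomic-feature partition with promoter > exon >
intron > intergenic precedence, ChIP occupancy under a >= 75 bp overlap
rule (peaks straddling more than one DHS are excluded), region-specificity
by subtraction, and pairwise peak-overlap matrices with average-linkage
hierarchical clustering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .util import count_overlaps_min_bp, overlap_stats, sort_intervals

PROMOTER_UPSTREAM = 1_000
OCCUPANCY_MIN_OVERLAP = 75
MAPPING_MIN_OVERLAP = 25
PROXIMAL_CUT = 2_500


def build_master_list(peak_sets: dict, representative: str = "union") -> pd.DataFrame:
    """Merge named peak sets into a sorted, non-overlapping master list.

    peak_sets maps sample label -> interval DataFrame. Returns a DataFrame
    (dhs_id, chrom, start, end, source_samples) where each master interval
    is the union span of the transitively overlapping contributing peaks
    (representative="union", idempotent: rebuilding from the output
    reproduces it) or a fixed 150-bp interval centered on the union
    midpoint (representative="centroid150").
    """
    if representative not in ("union", "centroid150"):
        raise ValueError("representative must be 'union' or 'centroid150'")
    frames = []
    for name, df in peak_sets.items():
        sub = df[["chrom", "start", "end"]].copy()
        sub["source"] = name
        frames.append(sub)
    allp = sort_intervals(pd.concat(frames, ignore_index=True))
    rows = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        srcs = grp["source"].to_numpy()
        run_s, run_e = starts[0], ends[0]
        run_src = {srcs[0]}
        for s, e, src in zip(starts[1:], ends[1:], srcs[1:]):
            if s < run_e:
                run_e = max(run_e, e)
                run_src.add(src)
            else:
                rows.append((chrom, run_s, run_e, ",".join(sorted(run_src))))
                run_s, run_e, run_src = s, e, {src}
        rows.append((chrom, run_s, run_e, ",".join(sorted(run_src))))
    master = pd.DataFrame(rows, columns=["chrom", "start", "end", "source_samples"])
    if representative == "centroid150":
        mid = (master["start"] + master["end"]) // 2
        master["start"] = (mid - 75).clip(lower=0)
        master["end"] = master["start"] + 150
    master.insert(0, "dhs_id", [f"MD{i:06d}" for i in range(len(master))])
    return master


def max_density_per_sample(master: pd.DataFrame, tracks_by_sample: dict) -> pd.DataFrame:
    """Raw density matrix: entry (DHS, sample) is the maximum tags-per-million
    window density over windows intersecting the DHS; 0 if none intersect."""
    mat = pd.DataFrame(0.0, index=master["dhs_id"], columns=list(tracks_by_sample))
    for sample, tracks in tracks_by_sample.items():
        for chrom, grp in master.groupby("chrom", sort=False):
            if chrom not in tracks:
                continue
            track = tracks[chrom]
            dens = track.density
            wl, step = track.window_len, track.step
            n_win = len(dens)
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            # windows [w, w+wl) intersecting [s, e): w in (s-wl, e)
            i0 = np.clip(s // step - (wl // step), 0, n_win)
            i1 = np.clip(-(-e // step), 0, n_win)
            vals = np.zeros(len(grp))
            for j, (a, b, qs, qe) in enumerate(zip(i0, i1, s, e)):
                a = int(a)
                b = int(b)
                # refine: keep windows truly intersecting
                w = np.arange(a, b) * step
                keep = (w + wl > qs) & (w < qe)
                if keep.any():
                    vals[j] = dens[a:b][keep].max()
            mat.loc[grp["dhs_id"], sample] = vals
    return mat


def promoter_windows(tss: pd.DataFrame, upstream: int = PROMOTER_UPSTREAM) -> pd.DataFrame:
    """Strand-aware upstream windows: [tss-upstream, tss) on '+',
    [tss+1, tss+upstream+1) on '-'."""
    if not set(tss["strand"]).issubset({"+", "-"}):
        raise ValueError("TSS strands must be '+' or '-'")
    plus = tss["strand"] == "+"
    start = np.where(plus, tss["position"] - upstream, tss["position"] + 1)
    end = np.where(plus, tss["position"], tss["position"] + upstream + 1)
    win = pd.DataFrame({"chrom": tss["chrom"], "start": start.clip(min=0), "end": end})
    return sort_intervals(win)


def classify_promoter(master: pd.DataFrame, tss: pd.DataFrame, upstream: int = PROMOTER_UPSTREAM) -> pd.Series:
    """True for master DHSs intersecting any strand-aware 1-kb upstream
    window of a TSS."""
    from .util import merge_intervals

    win = merge_intervals(promoter_windows(tss, upstream))
    n_hits, _, _ = overlap_stats(master, win)
    return pd.Series(n_hits > 0, index=master["dhs_id"].to_numpy(), name="promoter")


def genomic_partition(
    master: pd.DataFrame,
    tss: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
    introns: pd.DataFrame | None = None,
    upstream: int = PROMOTER_UPSTREAM,
    proximal_cut: int = PROXIMAL_CUT,
) -> pd.Series:
    """Assign each DHS exactly one category with precedence
    promoter > exon > intron > intergenic; intergenic is split at
    proximal_cut bp from the nearest TSS into proximal/distal."""
    from .util import merge_intervals

    n = len(master)
    cat = np.array(["distal_intergenic"] * n, dtype=object)
    for name, df in (("exon", exons), ("intron", introns)):
        if df is None:
            warnings.warn(f"no {name} annotation provided; class unused", stacklevel=2)
    if tss is None:
        warnings.warn("no TSS annotation provided; promoter/proximal unused", stacklevel=2)

    if introns is not None and len(introns):
        hits, _, _ = overlap_stats(master, merge_intervals(sort_intervals(introns)))
        cat[hits > 0] = "intron"
    if exons is not None and len(exons):
        hits, _, _ = overlap_stats(master, merge_intervals(sort_intervals(exons)))
        cat[hits > 0] = "exon"
    if tss is not None and len(tss):
        win = merge_intervals(promoter_windows(tss, upstream))
        hits, _, _ = overlap_stats(master, win)
        cat[hits > 0] = "promoter"
        # proximal/distal split for intergenic DHSs
        interg = np.flatnonzero((cat == "distal_intergenic"))
        tpos = {c: np.sort(g["position"].to_numpy()) for c, g in tss.groupby("chrom")}
        for i in interg:
            row = master.iloc[i]
            pos = tpos.get(row.chrom)
            if pos is None or len(pos) == 0:
                continue
            j = np.searchsorted(pos, row.start)
            cands = pos[max(j - 1, 0) : j + 2]
            dist = np.min(
                np.where(
                    (cands >= row.start) & (cands < row.end),
                    0,
                    np.minimum(np.abs(cands - row.start), np.abs(cands - (row.end - 1))),
                )
            )
            if dist <= proximal_cut:
                cat[i] = "proximal_intergenic"
    return pd.Series(cat, index=master["dhs_id"].to_numpy(), name="category")


def occupancy(
    master: pd.DataFrame,
    chip_peaks: pd.DataFrame,
    factor: str = "TF",
    min_overlap: int = OCCUPANCY_MIN_OVERLAP,
):
    """ChIP occupancy calls under the >= min_overlap bp rule.

    A peak overlapping exactly one master DHS by >= min_overlap marks that
    DHS occupied; peaks overlapping more than one DHS that deeply are
    excluded (tallied); peaks qualifying for none are tallied as
    non-overlapping. Returns (per-DHS status DataFrame, counts dict).
    """
    peaks = sort_intervals(chip_peaks[["chrom", "start", "end"]])
    counts, unique_idx = count_overlaps_min_bp(peaks, master, min_overlap)
    n_multi = int((counts > 1).sum())
    n_none = int((counts == 0).sum())
    occupied_rows = unique_idx[counts == 1]
    occ_ids = master.loc[occupied_rows, "dhs_id"] if len(occupied_rows) else pd.Series([], dtype=object)
    # per-peak overlap bp for the occupied assignments
    _, max_ov, _ = overlap_stats(peaks, master)
    calls = pd.DataFrame(
        {
            "dhs_id": master["dhs_id"].to_numpy(),
            "factor": factor,
            "status": np.where(
                master["dhs_id"].isin(set(occ_ids)), "occupied", "unoccupied"
            ),
        }
    )
    per_peak = pd.DataFrame(
        {
            "chrom": peaks["chrom"],
            "start": peaks["start"],
            "end": peaks["end"],
            "n_dhs_hit": counts,
            "overlap_bp": max_ov,
            "dhs_id": [
                master.loc[i, "dhs_id"] if i >= 0 else "" for i in unique_idx
            ],
        }
    )
    tally = {
        "factor": factor,
        "total_peaks": len(peaks),
        "occupying_peaks": int((counts == 1).sum()),
        "non_overlapping": n_none,
        "multi_overlap_excluded": n_multi,
        "occupied_dhs": int(calls["status"].eq("occupied").sum()),
    }
    return calls, per_peak, tally


def subtract_specific(
    target: pd.DataFrame, others: list, min_overlap: int = MAPPING_MIN_OVERLAP
) -> pd.DataFrame:
    """Target DHSs with < min_overlap bp intersection with every DHS in every
    other set (region-specific / cross-study subtraction)."""
    if not others:
        warnings.warn("no comparison sets; target returned unchanged", stacklevel=2)
        return target.copy()
    keep = np.ones(len(target), dtype=bool)
    tgt = target.reset_index(drop=True)
    for other in others:
        _, max_ov, _ = overlap_stats(tgt, sort_intervals(other[["chrom", "start", "end"]]))
        keep &= max_ov < min_overlap
    return tgt[keep].reset_index(drop=True)


def pairwise_overlap_matrix(sets: dict):
    """Fraction-of-overlapping-peaks matrix plus average-linkage dendrogram.

    Entry (A, B) = fraction of A's peaks overlapping any peak of B by
    >= 1 bp (asymmetric); clustering uses distance 1 - symmetrized mean.
    Returns (matrix DataFrame, linkage array or None, leaf-order list).
    """
    names = [n for n in sets]
    empty = [n for n in names if len(sets[n]) == 0]
    if empty:
        warnings.warn(f"empty sets excluded from clustering: {empty}", stacklevel=2)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    merged = {
        n: sort_intervals(sets[n][["chrom", "start", "end"]]) for n in names
    }
    from .util import merge_intervals

    for a in names:
        for b in names:
            if a == b:
                mat.loc[a, b] = 1.0
                continue
            if len(sets[a]) == 0:
                continue
            hits, _, _ = overlap_stats(merged[a], merge_intervals(merged[b]))
            mat.loc[a, b] = float((hits > 0).mean())
    keep = [n for n in names if n not in empty]
    if len(keep) < 2:
        return mat, None, keep
    sym = (mat.loc[keep, keep].to_numpy() + mat.loc[keep, keep].to_numpy().T) / 2
    dist = 1.0 - sym
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [keep[i] for i in hierarchy.leaves_list(Z)]
    return mat, Z, order
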
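"""Shared helpers: interval algebra on sorted arrays, BED/TSV I/O, misc.

Intervals are 0-based, half-open (BED convention) everywhere. Interval sets
are pandas DataFrames with at least ``chrom`` (str), ``start`` (int),
``end`` (int) columns, sorted per chromosome by start.
"""

from __future__ import annotations

import gzip
import hashlib
import io
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def percent(k: int, n: int, ndigits: int = 0) -> float:
    """Percentage 100*k/n rounded to `ndigits` (round-half-to-even)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, ndigits) if ndigits else float(round(100.0 * k / n))


def largest_remainder_counts(n: int, proportions: Iterable[float]) -> np.ndarray:
    """Integer counts summing to n, apportioned by the largest-remainder rule.

    Deterministic; ties broken by category order.
    """
    props = np.asarray(list(proportions), dtype=float)
    if props.min() < 0 or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    quota = n * props
    counts = np.floor(quota).astype(int)
    short = n - counts.sum()
    if short:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def config_hash(mapping: Mapping) -> str:
    text = ";".join(f"{k}={mapping[k]}" for k in sorted(map(str, mapping)))
    return hashlib.sha1(text.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# interval algebra (sorted numpy arrays; subjects non-overlapping)
# ---------------------------------------------------------------------------

def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals that overlap (or lie within `gap` bp) per chromosome.

    gap=0 merges strictly overlapping intervals only; abutting intervals
    ([a,b) and [b,c)) stay separate under gap=0.
    """
    if df.empty:
        return df[BED_COLS].copy()
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        run_start = starts[0]
        run_end = ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s < run_end or (gap > 0 and s <= run_end + gap):
                run_end = max(run_end, e)
            else:
                out.append((chrom, run_start, run_end))
                run_start, run_end = s, e
        out.append((chrom, run_start, run_end))
    return pd.DataFrame(out, columns=BED_COLS)


def _check_disjoint(starts: np.ndarray, ends: np.ndarray) -> None:
    if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
        raise ValueError("subject intervals must be non-overlapping within a chromosome")


def overlap_stats(query: pd.DataFrame, subject: pd.DataFrame):
    """Per query interval: (#subject intervals overlapped >=1bp, max single-
    interval overlap in bp, index into subject of the best overlap or -1).

    Subject must be internally non-overlapping per chromosome (checked).
    Returns three numpy arrays aligned with query rows.
    """
    n = len(query)
    n_hits = np.zeros(n, dtype=int)
    max_ov = np.zeros(n, dtype=int)
    best = np.full(n, -1, dtype=int)
    if n == 0 or subject.empty:
        return n_hits, max_ov, best
    subj_by_chrom = {}
    for chrom, grp in subject.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        starts = grp["start"].to_numpy()[order]
        ends = grp["end"].to_numpy()[order]
        _check_disjoint(starts, ends)
        subj_by_chrom[chrom] = (starts, ends, grp.index.to_numpy()[order])
    qpos = {c: np.flatnonzero(query["chrom"].to_numpy() == c) for c in subj_by_chrom}
    for chrom, rows in qpos.items():
        if rows.size == 0:
            continue
        starts, ends, sidx = subj_by_chrom[chrom]
        qs = query["start"].to_numpy()[rows]
        qe = query["end"].to_numpy()[rows]
        # subjects overlapping [qs,qe): those with end > qs and start < qe
        i0 = np.searchsorted(ends, qs, side="right")
        i1 = np.searchsorted(starts, qe, side="left")
        for j, (a, b, s, e, r) in enumerate(zip(i0, i1, qs, qe, rows)):
            if b <= a:
                continue
            ov = np.minimum(ends[a:b], e) - np.maximum(starts[a:b], s)
            ov = ov[ov > 0]
            if ov.size:
                n_hits[r] = ov.size
                k = int(np.argmax(np.minimum(ends[a:b], e) - np.maximum(starts[a:b], s)))
                max_ov[r] = int(ov.max())
                best[r] = sidx[a + k]
    return n_hits, max_ov, best


def count_overlaps_min_bp(query: pd.DataFrame, subject: pd.DataFrame, min_bp: int):
    """Per query row: (#subjects overlapped by >= min_bp, index of the unique
    such subject when the count is exactly 1, else -1)."""
    n = len(query)
    counts = np.zeros(n, dtype=int)
    unique_idx = np.full(n, -1, dtype=int)
    if n == 0 or subject.empty:
        return counts, unique_idx
    subj_by_chrom = {}
    for chrom, grp in subject.groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        starts = grp["start"].to_numpy()[order]
        ends = grp["end"].to_numpy()[order]
        _check_disjoint(starts, ends)
        subj_by_chrom[chrom] = (starts, ends, grp.index.to_numpy()[order])
    for chrom, (starts, ends, sidx) in subj_by_chrom.items():
        rows = np.flatnonzero(query["chrom"].to_numpy() == chrom)
        if rows.size == 0:
            continue
        qs = query["start"].to_numpy()[rows]
        qe = query["end"].to_numpy()[rows]
        i0 = np.searchsorted(ends, qs, side="right")
        i1 = np.searchsorted(starts, qe, side="left")
        for a, b, s, e, r in zip(i0, i1, qs, qe, rows):
            if b <= a:
                continue
            ov = np.minimum(ends[a:b], e) - np.maximum(starts[a:b], s)
            hit = np.flatnonzero(ov >= min_bp)
            counts[r] = hit.size
            if hit.size == 1:
                unique_idx[r] = sidx[a + hit[0]]
    return counts, unique_idx


def tags_in_intervals(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> int:
    """Count of sorted positions falling inside any of the sorted,
    non-overlapping [start, end) intervals."""
    if len(starts) == 0 or len(positions) == 0:
        return 0
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    return int((hi - lo).sum())


# ---------------------------------------------------------------------------
# I/O (gzip-capable by extension)
# ---------------------------------------------------------------------------

def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_bed(df: pd.DataFrame, path, score_col=None, name_col=None) -> None:
    """Write BED3/BED6. With score/name columns emits 6 columns
    (name '.', score 0 by default, strand from a 'strand' column or '.')."""
    with _open(path, "wt") as fh:
        for row in df.itertuples(index=False):
            d = row._asdict()
            fields = [d["chrom"], d["start"], d["end"]]
            if score_col or name_col or "strand" in d:
                fields += [
                    d.get(name_col, ".") if name_col else d.get("name", "."),
                    d.get(score_col, 0) if score_col else d.get("score", 0),
                    d.get("strand", "."),
                ]
            fh.write("\t".join(map(str, fields)) + "\n")


def read_bed(path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    with _open(path, "rt") as fh:
        df = pd.read_csv(io.StringIO(fh.read()), sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_tsv(df: pd.DataFrame, path, index=False) -> None:
    with _open(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    with _open(path, "rt") as fh:
        return pd.read_csv(fh, sep="\t", **kw)


def write_bedgraph(df: pd.DataFrame, path, value_col="count") -> None:
    with _open(path, "wt") as fh:
        for row in df.itertuples(index=False):
            d = row._asdict()
            fh.write(f"{d['chrom']}\t{d['start']}\t{d['end']}\t{d[value_col]}\n")


def write_flat_config(mapping: Mapping, path) -> None:
    with _open(path, "wt") as fh:
        for k in sorted(map(str, mapping)):
            fh.write(f"{k}={mapping[k]}\n")


def read_flat_config(path) -> dict:
    out = {}
    with _open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out
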
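"""Cross-species DHS conservation categories and region comparisons.

Each DHS of the source species is classified through an orthology interval
map: *unalignable* if no orthologous sequence exists, *shared* if the
mapped target interval overlaps a partner-species DHS by at least 25 bp,
and *diverged* (sequence conserved but inactive) otherwise. Category
distributions across regions are compared by pairwise Pearson chi-squared
on the 2 x 3 count tables (no continuity correction).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .util import overlap_stats, sort_intervals

MIN_OVERLAP = 25
CATEGORIES = ("shared", "diverged", "unalignable")


def categorize(
    dhs_set: pd.DataFrame,
    ortho_map: pd.DataFrame,
    partner_dhs: pd.DataFrame,
    min_overlap: int = MIN_OVERLAP,
) -> pd.DataFrame:
    """Assign each source DHS one conservation category.

    A DHS is mapped when an orthology record's source interval overlaps it;
    split mappings are collapsed to the record with the largest overlap.
    Returns a DataFrame (dhs_id, category).
    """
    dhs = dhs_set.reset_index(drop=True)
    ids = dhs["dhs_id"] if "dhs_id" in dhs.columns else pd.Series(
        [f"D{i:06d}" for i in range(len(dhs))]
    )
    src = ortho_map.rename(
        columns={"src_chrom": "chrom", "src_start": "start", "src_end": "end"}
    )[["chrom", "start", "end"]].copy()
    src = src.reset_index(drop=True)
    order = np.lexsort((src["start"].to_numpy(), src["chrom"].to_numpy()))
    src_sorted = src.iloc[order].reset_index(drop=True)
    n_hits, _, best = overlap_stats(dhs, src_sorted)
    partner_sorted = sort_intervals(partner_dhs[["chrom", "start", "end"]]) if len(partner_dhs) else partner_dhs
    cats = []
    for i in range(len(dhs)):
        if n_hits[i] == 0:
            cats.append("unalignable")
            continue
        rec = ortho_map.iloc[order[best[i]]]
        tgt = pd.DataFrame(
            {"chrom": [rec["tgt_chrom"]], "start": [rec["tgt_start"]], "end": [rec["tgt_end"]]}
        )
        if len(partner_sorted):
            _, max_ov, _ = overlap_stats(tgt, partner_sorted)
            cats.append("shared" if max_ov[0] >= min_overlap else "diverged")
        else:
            cats.append("diverged")
    return pd.DataFrame({"dhs_id": ids, "category": cats})


def category_distribution(records_by_region: dict):
    """Region x category count table and row proportions."""
    regions = []
    counts = []
    for region, rec in records_by_region.items():
        if len(rec) == 0:
            warnings.warn(f"region {region!r} is empty; dropped", stacklevel=2)
            continue
        vc = rec["category"].value_counts()
        counts.append([int(vc.get(c, 0)) for c in CATEGORIES])
        regions.append(region)
    table = pd.DataFrame(counts, index=regions, columns=list(CATEGORIES))
    props = table.div(table.sum(axis=1), axis=0)
    return table, props


def pairwise_chisq(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson chi-squared p-values between region rows.

    Each pair forms a 2 x 3 contingency table (df = 2 when all categories
    are populated); no continuity correction; diagonal is 1.
    """
    regions = list(table.index)
    out = pd.DataFrame(1.0, index=regions, columns=regions)
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            sub = table.loc[[a, b]].to_numpy(dtype=float)
            sub = sub[:, sub.sum(axis=0) > 0]  # drop empty categories
            exp = np.outer(sub.sum(axis=1), sub.sum(axis=0)) / sub.sum()
            if (exp < 5).any():
                warnings.warn(
                    f"low expected counts in pair ({a}, {b}); chi-squared may be inaccurate",
                    stacklevel=2,
                )
            if np.allclose(sub[0] / sub[0].sum(), sub[1] / sub[1].sum()):
                p = 1.0
            else:
                _, p, _, _ = stats.chi2_contingency(sub, correction=False)
            out.loc[a, b] = out.loc[b, a] = float(p)
    return out
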
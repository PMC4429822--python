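"""DNase I hotspot and peak detection with simulated-null FDR calibration.

Tags are summed within 150-bp windows advanced in 20-bp steps. Each window
is scored against a binomial local-background model: with ``t`` tags in the
surrounding local background of length ``L`` (default 50 kb centered on the
window), the window count ``c`` gets the upper tail P(X >= c) for
X ~ Binomial(t, 150/L). Significant windows are merged into hotspots,
hotspots are internally scanned for local maxima to emit fixed 150-bp
peaks, and the significance threshold is calibrated so that hotspot calls
on uniform random tags at equal depth amount to less than a target fraction
(default 1%) of the observed calls. Library quality is summarized by the
SPOT score, the fraction of tags falling inside hotspots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .util import tags_in_intervals

WINDOW_LEN = 150
STEP = 20
BACKGROUND_LEN = 50_000
DEFAULT_TARGET_DEPTH = 25_000_000  # reference full-scale sequencing depth
P_FLOOR = 1e-300


@dataclass
class TagSet:
    """Aligned cleavage tag coordinates for one sample."""

    sample_id: str
    tags: pd.DataFrame  # chrom, pos, strand; sorted by (chrom, pos)
    genome: dict  # chrom -> length

    @property
    def depth(self) -> int:
        return len(self.tags)

    def positions(self, chrom: str) -> np.ndarray:
        sub = self.tags[self.tags["chrom"] == chrom]
        return np.sort(sub["pos"].to_numpy())


@dataclass
class CutWindowTrack:
    """Per-window tag counts for one chromosome (fixed start grid)."""

    chrom: str
    window_len: int
    step: int
    counts: np.ndarray  # tag count per window, windows start at 0, step apart
    total_tags: int  # sample depth used for per-million normalization
    positions: np.ndarray | None = None  # sorted tag positions (for exact local totals)
    chrom_length: int | None = None

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(len(self.counts)) * self.step

    @property
    def density(self) -> np.ndarray:
        """Counts normalized to tags-per-million sequencing depth."""
        return self.counts * (1e6 / max(self.total_tags, 1))


@dataclass
class FdrCalibration:
    threshold: float
    observed_hotspots: int
    simulated_hotspots: float
    fdr_estimate: float
    spot_observed: float
    seed: int
    n_replicates: int = 1


def downsample_tags(tagset: TagSet, target_depth: int = DEFAULT_TARGET_DEPTH, seed: int = 0) -> TagSet:
    """Random sampling without replacement down to exactly target_depth tags."""
    if target_depth > tagset.depth:
        raise ValueError("target_depth exceeds available depth")
    if target_depth == tagset.depth:
        return TagSet(tagset.sample_id, tagset.tags.copy(), tagset.genome)
    rng = np.random.default_rng(seed % (2**31))
    keep = rng.choice(tagset.depth, size=target_depth, replace=False)
    sub = tagset.tags.iloc[np.sort(keep)].reset_index(drop=True)
    return TagSet(tagset.sample_id, sub, tagset.genome)


def count_cuts(tagset: TagSet, window_len: int = WINDOW_LEN, step: int = STEP) -> dict:
    """Per-chromosome CutWindowTrack of tag counts in sliding windows.

    A tag at position p is counted in window [s, s+window_len) iff
    s <= p < s+window_len; strand is ignored.
    """
    tracks = {}
    for chrom, length in tagset.genome.items():
        pos = tagset.positions(chrom)
        n_win = max((length - window_len) // step + 1, 0)
        starts = np.arange(n_win) * step
        counts = (
            np.searchsorted(pos, starts + window_len, side="left")
            - np.searchsorted(pos, starts, side="left")
        ).astype(np.int32)
        tracks[chrom] = CutWindowTrack(
            chrom=chrom,
            window_len=window_len,
            step=step,
            counts=counts,
            total_tags=tagset.depth,
            positions=pos,
            chrom_length=length,
        )
    return tracks


def binomial_window_pvalue(window_count, local_total, window_len=WINDOW_LEN, background_len=BACKGROUND_LEN):
    """Upper-tail P(X >= window_count), X ~ Binomial(local_total, wl/bl).

    Vectorized over window_count/local_total.
    """
    if window_len >= background_len:
        raise ValueError("background_len must exceed window_len")
    k = np.asarray(window_count)
    n = np.asarray(local_total)
    if np.any(n < k):
        raise ValueError("local_total must be >= window_count")
    p = window_len / background_len
    out = stats.binom.sf(k - 1, n, p)
    return float(out) if out.ndim == 0 else out


def window_pvalues(track: CutWindowTrack, background_len: int = BACKGROUND_LEN) -> np.ndarray:
    """Per-window binomial p-value against the local background.

    The local total is the exact tag count within background_len centered on
    the window (clipped to the chromosome) when tag positions are attached
    to the track; otherwise it is estimated from overlapping window counts.
    """
    starts = track.window_starts
    centers = starts + track.window_len // 2
    half = background_len // 2
    length = track.chrom_length or (starts[-1] + track.window_len if len(starts) else 0)
    lo = np.clip(centers - half, 0, length)
    hi = np.clip(centers + half, 0, length)
    if track.positions is not None:
        local = (
            np.searchsorted(track.positions, hi, side="left")
            - np.searchsorted(track.positions, lo, side="left")
        )
    else:
        # each tag appears in ~window_len/step overlapping windows
        csum = np.concatenate([[0], np.cumsum(track.counts, dtype=np.float64)])
        i0 = np.clip(lo // track.step, 0, len(track.counts))
        i1 = np.clip(hi // track.step, 0, len(track.counts))
        local = np.rint((csum[i1] - csum[i0]) * track.step / track.window_len).astype(int)
    local = np.maximum(local, track.counts)
    return binomial_window_pvalue(track.counts, local, track.window_len, background_len)


def _merge_significant(starts: np.ndarray, window_len: int, step: int):
    """Group sorted significant window starts into hotspot spans; merge when
    window intervals overlap or leave a gap of at most one step."""
    if len(starts) == 0:
        return []
    breaks = np.flatnonzero(np.diff(starts) > window_len + step)
    bounds = np.concatenate([[0], breaks + 1, [len(starts)]])
    return [(int(starts[a]), int(starts[b - 1]) + window_len) for a, b in zip(bounds[:-1], bounds[1:])]


def call_hotspots(
    tracks: dict,
    threshold: float,
    background_len: int = BACKGROUND_LEN,
    pvals: dict | None = None,
) -> pd.DataFrame:
    """Merge significant windows (p <= threshold) into maximal hotspots.

    Returns a DataFrame (chrom, start, end, tag_count, p_min) sorted by
    coordinate; hotspot significance is the minimum window p-value inside.
    """
    rows = []
    for chrom, track in tracks.items():
        pv = pvals[chrom] if pvals is not None else window_pvalues(track, background_len)
        sig = np.flatnonzero(pv <= threshold)
        if sig.size == 0:
            continue
        starts = track.window_starts[sig]
        spans = _merge_significant(starts, track.window_len, track.step)
        sig_starts = starts
        for s, e in spans:
            inside = (sig_starts >= s) & (sig_starts <= e - track.window_len)
            p_min = float(pv[sig[inside]].min())
            if track.positions is not None:
                cnt = int(
                    np.searchsorted(track.positions, e, side="left")
                    - np.searchsorted(track.positions, s, side="left")
                )
            else:
                cnt = int(track.counts[sig[inside]].max())
            rows.append((chrom, s, e, cnt, p_min))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "tag_count", "p_min"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def call_peaks(hotspots: pd.DataFrame, tracks: dict) -> pd.DataFrame:
    """Emit fixed 150-bp peaks at local maxima of window counts inside each
    hotspot, greedily from the highest maximum, skipping overlaps.

    Every hotspot yields at least one peak. Returns (chrom, start, end,
    summit, density, hotspot_index).
    """
    rows = []
    for hs_idx, hs in enumerate(hotspots.itertuples(index=False)):
        track = tracks[hs.chrom]
        wl, step = track.window_len, track.step
        i0 = int(np.ceil(hs.start / step))
        i1 = int((hs.end - wl) // step)
        i1 = min(i1, len(track.counts) - 1)
        if i1 < i0:
            i0 = i1 = min(int(hs.start // step), len(track.counts) - 1)
        c = track.counts[i0 : i1 + 1].astype(float)
        # local maxima: >= left neighbor, > right neighbor (leftmost of plateau)
        left = np.concatenate([[-np.inf], c[:-1]])
        right = np.concatenate([c[1:], [-np.inf]])
        maxima = np.flatnonzero((c >= left) & (c > right))
        if maxima.size == 0:
            maxima = np.array([int(np.argmax(c))])
        order = maxima[np.argsort(-c[maxima], kind="stable")]
        emitted = []
        dens = track.density
        for m in order:
            s = (i0 + m) * step
            if any(abs(s - es) < wl for es in emitted):
                continue
            emitted.append(s)
            rows.append((hs.chrom, s, s + wl, s + wl // 2, float(dens[i0 + m]), hs_idx))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "density", "hotspot_index"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def spot_score(tagset: TagSet, hotspots: pd.DataFrame) -> float:
    """SPOT (signal portion of tags): fraction of tags inside hotspots."""
    if tagset.depth == 0:
        raise ValueError("empty TagSet has no SPOT score")
    inside = 0
    for chrom, grp in hotspots.groupby("chrom", sort=False):
        pos = tagset.positions(chrom)
        grp = grp.sort_values("start")
        inside += tags_in_intervals(pos, grp["start"].to_numpy(), grp["end"].to_numpy())
    return inside / tagset.depth


def simulate_uniform_tags(depth: int, mappable: pd.DataFrame, genome: dict, seed: int) -> TagSet:
    """Uniform random tags over the mappable regions at the given depth."""
    if mappable.empty:
        raise ValueError("mappable region set is empty")
    rng = np.random.default_rng(seed % (2**31))
    lens = (mappable["end"] - mappable["start"]).to_numpy()
    pick = rng.choice(len(mappable), size=depth, p=lens / lens.sum())
    offs = (rng.random(depth) * lens[pick]).astype(np.int64)
    chroms = mappable["chrom"].to_numpy()[pick]
    pos = mappable["start"].to_numpy()[pick] + offs
    strands = rng.choice(["+", "-"], size=depth)
    tags = pd.DataFrame({"chrom": chroms, "pos": pos, "strand": strands})
    tags = tags.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return TagSet("null", tags, genome)


def _hotspot_count_at(neglogp_by_chrom: dict, starts_by_chrom: dict, x: float, window_len: int, step: int) -> int:
    total = 0
    for chrom, nlp in neglogp_by_chrom.items():
        sig = nlp >= x
        if not sig.any():
            continue
        total += len(_merge_significant(starts_by_chrom[chrom][sig], window_len, step))
    return total


def estimate_fdr(
    tagset: TagSet,
    mappable: pd.DataFrame,
    threshold: float,
    seed: int = 0,
    background_len: int = BACKGROUND_LEN,
    n_replicates: int = 1,
) -> FdrCalibration:
    """FDR estimate at a fixed threshold: hotspots called on uniform random
    tags at equal depth, divided by hotspots called on the observed tags."""
    tracks = count_cuts(tagset)
    obs = call_hotspots(tracks, threshold, background_len)
    sim_counts = []
    for r in range(n_replicates):
        null = simulate_uniform_tags(tagset.depth, mappable, tagset.genome, seed + r)
        null_tracks = count_cuts(null)
        sim_counts.append(len(call_hotspots(null_tracks, threshold, background_len)))
    sim = float(np.mean(sim_counts))
    if len(obs) == 0:
        warnings.warn("zero observed hotspots; FDR reported as 1.0", stacklevel=2)
        fdr = 1.0
    else:
        fdr = sim / len(obs)
    return FdrCalibration(
        threshold=threshold,
        observed_hotspots=len(obs),
        simulated_hotspots=sim,
        fdr_estimate=fdr,
        spot_observed=spot_score(tagset, obs) if len(obs) else 0.0,
        seed=seed,
        n_replicates=n_replicates,
    )


def calibrate_threshold(
    tagset: TagSet,
    mappable: pd.DataFrame,
    target_fdr: float = 0.01,
    seed: int = 0,
    background_len: int = BACKGROUND_LEN,
    n_replicates: int = 1,
    lo: float = 2.0,
    hi: float = 12.0,
    n_iter: int = 25,
) -> FdrCalibration:
    """Bisection search over -log10 p in [lo, hi] for the loosest threshold
    whose simulated-null FDR estimate is below target_fdr.

    Window p-values for the observed sample and for each null replicate are
    computed once; thresholding and merging are re-evaluated per iteration.
    """
    tracks = count_cuts(tagset)
    obs_nlp, obs_starts = {}, {}
    for chrom, track in tracks.items():
        pv = np.maximum(window_pvalues(track, background_len), P_FLOOR)
        obs_nlp[chrom] = -np.log10(pv)
        obs_starts[chrom] = track.window_starts
    null_sets = []
    for r in range(n_replicates):
        null = simulate_uniform_tags(tagset.depth, mappable, tagset.genome, seed + r)
        nt = count_cuts(null)
        nlp, nst = {}, {}
        for chrom, track in nt.items():
            pv = np.maximum(window_pvalues(track, background_len), P_FLOOR)
            nlp[chrom] = -np.log10(pv)
            nst[chrom] = track.window_starts
        null_sets.append((nlp, nst))

    wl, step = WINDOW_LEN, STEP

    def fdr_at(x: float) -> tuple[float, int, float]:
        n_obs = _hotspot_count_at(obs_nlp, obs_starts, x, wl, step)
        n_sim = float(
            np.mean([_hotspot_count_at(nlp, nst, x, wl, step) for nlp, nst in null_sets])
        )
        return n_sim / max(n_obs, 1), n_obs, n_sim

    f_lo, n_obs_lo, n_sim_lo = fdr_at(lo)
    if f_lo < target_fdr:
        x_star, fdr_star, n_obs_star, n_sim_star = lo, f_lo, n_obs_lo, n_sim_lo
    else:
        a, b = lo, hi
        x_star = hi
        fdr_star, n_obs_star, n_sim_star = fdr_at(hi)
        for _ in range(n_iter):
            mid = 0.5 * (a + b)
            f_mid, n_obs_mid, n_sim_mid = fdr_at(mid)
            if f_mid < target_fdr:
                b = mid
                x_star, fdr_star, n_obs_star, n_sim_star = mid, f_mid, n_obs_mid, n_sim_mid
            else:
                a = mid
    threshold = 10.0 ** (-x_star)
    obs_hs = call_hotspots(tracks, threshold, background_len)
    return FdrCalibration(
        threshold=threshold,
        observed_hotspots=n_obs_star,
        simulated_hotspots=n_sim_star,
        fdr_estimate=fdr_star,
        spot_observed=spot_score(tagset, obs_hs) if len(obs_hs) else 0.0,
        seed=seed,
        n_replicates=n_replicates,
    )
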
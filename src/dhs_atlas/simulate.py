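"""Synthetic DNase-seq inputs with known ground truth.

Emulates a three-stage developmental design (default stages P0, P7, Adult):
a uniform background of DNase I cleavage tags plus planted hypersensitive
sites (DHSs) whose per-stage intensity follows one of four temporal
archetypes — early, mid, late, constitutive. Companion generators fabricate
ChIP-seq peak sets with a controlled DHS-overlap fraction, genome-wide motif
hit tables with controlled per-archetype enrichment odds, and cross-species
orthology maps with controlled shared/diverged/unalignable proportions.
Everything is interval-based (no sequence content) and bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import largest_remainder_counts, sort_intervals

ARCHETYPES = ("early", "mid", "late", "constitutive")

#: Relative accessibility of each archetype at the three ordered stages.
#: Shapes: early peaks at stage 1 and decays, mid peaks at stage 2, late
#: rises to stage 3, constitutive is flat.
ARCHETYPE_WEIGHTS = {
    "early": (1.0, 0.4, 0.15),
    "mid": (0.3, 1.0, 0.3),
    "late": (0.15, 0.4, 1.0),
    "constitutive": (1.0, 1.0, 1.0),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic genome and sequencing design.

    Defaults define the demo scale: a 2 x 5 Mb genome with 2,000 planted
    DHSs of 200 bp at 10-fold cleavage enrichment, 1 M tags per sample.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_true_dhs: int = 2_000
    dhs_width: int = 200
    archetype_mix: dict = field(
        default_factory=lambda: {"early": 0.30, "mid": 0.25, "late": 0.25, "constitutive": 0.20}
    )
    enrichment_fold: float = 10.0
    depth: int = 1_000_000
    stages: tuple = ("P0", "P7", "Adult")
    n_tss: int = 400
    min_dhs_gap: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.n_chroms <= 0 or self.chrom_length <= 0 or self.dhs_width <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")
        mix = self.archetype_mix
        if set(mix) != set(ARCHETYPES):
            raise ValueError(f"archetype_mix must cover {ARCHETYPES}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype_mix proportions must sum to 1")
        per_chrom = -(-self.n_true_dhs // self.n_chroms)
        if per_chrom * (self.dhs_width + self.min_dhs_gap) >= self.chrom_length:
            raise ValueError("planted DHSs do not fit in the genome")

    @property
    def genome(self) -> dict:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def archetype_weight(self, archetype: str, stage: str) -> float:
        return ARCHETYPE_WEIGHTS[archetype][self.stages.index(stage)]


@dataclass
class SimTruth:
    """Ground truth carried alongside synthetic data sets."""

    true_dhs: pd.DataFrame  # chrom, start, end, archetype, per-stage weight cols
    tss: pd.DataFrame  # gene, chrom, position, strand
    chip_truth: dict = field(default_factory=dict)  # factor -> peak df with overlaps_dhs flag
    motif_truth: pd.DataFrame | None = None  # DHS x TF presence flags
    orthology_truth: pd.Series | None = None  # DHS id -> category
    config: SimConfig | None = None


def _plant_nonoverlapping(rng, n, width, gap, length) -> np.ndarray:
    """n sorted, pairwise non-overlapping starts with >= gap bp spacing."""
    slack = length - n * (width + gap)
    if slack <= n:
        raise ValueError("not enough room to plant intervals")
    offs = np.sort(rng.choice(slack, size=n, replace=False))
    return offs + np.arange(n) * (width + gap) + gap // 2


def simulate_truth(config: SimConfig) -> SimTruth:
    """Plant DHS intervals with archetype labels and TSS annotations."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = list(config.genome)
    counts = largest_remainder_counts(config.n_true_dhs, [1 / config.n_chroms] * config.n_chroms)
    rows = []
    for chrom, n in zip(chroms, counts):
        starts = _plant_nonoverlapping(rng, int(n), config.dhs_width, config.min_dhs_gap, config.chrom_length)
        for s in starts:
            rows.append((chrom, int(s), int(s) + config.dhs_width))
    dhs = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    arch_counts = largest_remainder_counts(
        len(dhs), [config.archetype_mix[a] for a in ARCHETYPES]
    )
    labels = np.repeat(ARCHETYPES, arch_counts)
    rng.shuffle(labels)
    dhs["archetype"] = labels
    dhs["dhs_id"] = [f"TD{i:06d}" for i in range(len(dhs))]
    for j, stage in enumerate(config.stages):
        dhs[f"w_{stage}"] = [ARCHETYPE_WEIGHTS[a][j] for a in labels]

    tss_rows = []
    tss_counts = largest_remainder_counts(config.n_tss, [1 / config.n_chroms] * config.n_chroms)
    g = 0
    for chrom, n in zip(chroms, tss_counts):
        pos = np.sort(rng.choice(config.chrom_length, size=int(n), replace=False))
        strands = rng.choice(["+", "-"], size=int(n))
        for p, st in zip(pos, strands):
            tss_rows.append((f"G{g:05d}", chrom, int(p), st))
            g += 1
    tss = pd.DataFrame(tss_rows, columns=["gene", "chrom", "position", "strand"])
    return SimTruth(true_dhs=dhs, tss=tss, config=config)


def simulate_tags(config: SimConfig, stage: str, truth: SimTruth | None = None, seed: int | None = None):
    """Draw exactly ``config.depth`` cleavage tags for one stage.

    Background tags fall uniformly over the genome at relative rate 1 per bp;
    tags inside a planted DHS fall at rate enrichment_fold x archetype
    weight for the requested stage. Returns (TagSet, SimTruth); the truth is
    derived solely from the config seed, so all stages share it.
    """
    from .hotspots import TagSet  # local import to avoid a cycle

    config.validate()
    if stage not in config.stages:
        raise ValueError(f"unknown stage {stage!r}")
    if truth is None:
        truth = simulate_truth(config)
    if seed is None:
        seed = config.seed * 1000 + 7 * (config.stages.index(stage) + 1)
    rng = np.random.default_rng(seed % (2**31))

    # region list per chromosome: background gaps (weight 1) + DHSs (weighted)
    seg_chrom, seg_start, seg_end, seg_w = [], [], [], []
    for chrom, length in config.genome.items():
        d = truth.true_dhs[truth.true_dhs["chrom"] == chrom]
        prev = 0
        for row in d.itertuples(index=False):
            if row.start > prev:
                seg_chrom.append(chrom)
                seg_start.append(prev)
                seg_end.append(row.start)
                seg_w.append(1.0)
            seg_chrom.append(chrom)
            seg_start.append(row.start)
            seg_end.append(row.end)
            seg_w.append(config.enrichment_fold * config.archetype_weight(row.archetype, stage))
            prev = row.end
        if prev < length:
            seg_chrom.append(chrom)
            seg_start.append(prev)
            seg_end.append(length)
            seg_w.append(1.0)
    seg_start = np.asarray(seg_start)
    seg_end = np.asarray(seg_end)
    seg_len = seg_end - seg_start
    mass = seg_len * np.asarray(seg_w)
    pmass = mass / mass.sum()

    exp_per_dhs = config.depth * (
        config.dhs_width * config.enrichment_fold / mass.sum()
    )
    if exp_per_dhs < 1:
        warnings.warn("expected in-DHS tag count < 1 per DHS at this depth", stacklevel=2)

    n_per_seg = rng.multinomial(config.depth, pmass)
    chrom_out, pos_out = [], []
    for c, s, e, n in zip(seg_chrom, seg_start, seg_end, n_per_seg):
        if n == 0:
            continue
        chrom_out.append(np.full(n, c, dtype=object))
        pos_out.append(rng.integers(s, e, size=n))
    chroms = np.concatenate(chrom_out)
    positions = np.concatenate(pos_out)
    strands = rng.choice(["+", "-"], size=config.depth)
    tags = pd.DataFrame({"chrom": chroms, "pos": positions, "strand": strands})
    tags = tags.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return TagSet(sample_id=f"sim_{stage}", tags=tags, genome=config.genome), truth


def simulate_chip_peaks(
    truth: SimTruth,
    overlap_fraction: float,
    n_peaks: int,
    seed: int = 0,
    factor: str = "TF",
    peak_width: int = 150,
    min_overlap: int = 75,
) -> pd.DataFrame:
    """Fabricate a ChIP peak set: round(overlap_fraction * n_peaks) peaks each
    overlap one true DHS by >= min_overlap bp; the rest intersect none."""
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    cfg = truth.config
    n_ov = int(round(overlap_fraction * n_peaks))  # round-half-to-even
    dhs = truth.true_dhs
    if n_ov > len(dhs):
        raise ValueError("more overlapping peaks requested than true DHSs")
    if min(peak_width, cfg.dhs_width) < min_overlap:
        raise ValueError("peak or DHS width below the required overlap")
    rng = np.random.default_rng(seed % (2**31))
    chosen = rng.choice(len(dhs), size=n_ov, replace=False)
    rows = []
    for i in chosen:
        d = dhs.iloc[i]
        center = (d.start + d.end) // 2
        rows.append((d.chrom, center - peak_width // 2, center - peak_width // 2 + peak_width, True))
    # non-overlapping peaks: uniform in background, rejected if touching a DHS
    n_bg = n_peaks - n_ov
    chroms = list(cfg.genome)
    starts_by_chrom = {
        c: dhs.loc[dhs["chrom"] == c, ["start", "end"]].to_numpy() for c in chroms
    }
    placed = 0
    while placed < n_bg:
        c = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, cfg.chrom_length - peak_width))
        iv = starts_by_chrom[c]
        if iv.size and ((iv[:, 0] < s + peak_width) & (iv[:, 1] > s)).any():
            continue
        rows.append((c, s, s + peak_width, False))
        placed += 1
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "overlaps_dhs"])
    peaks = sort_intervals(peaks)
    truth.chip_truth[factor] = peaks
    return peaks


def simulate_motif_hits(
    truth: SimTruth,
    tf_enrichment: dict,
    background_rate: float = 0.05,
    seed: int = 0,
    hit_width: int = 10,
    p_ceiling: float = 1e-4,
) -> pd.DataFrame:
    """Fabricate a motif hit table over the true DHSs.

    tf_enrichment maps TF name -> (target archetype, odds). Presence
    probability is background_rate outside the target archetype and
    min(1, background_rate * odds) inside it; each hit is an interval inside
    its DHS with a match p-value below p_ceiling.
    """
    rng = np.random.default_rng(seed % (2**31))
    dhs = truth.true_dhs
    arch = dhs["archetype"].to_numpy()
    rows = []
    presence = {}
    for tf, (target, odds) in tf_enrichment.items():
        if odds < 1:
            raise ValueError("odds must be >= 1")
        p_in = background_rate * odds
        if p_in > 1:
            warnings.warn(f"{tf}: background_rate*odds > 1; clamped to 1", stacklevel=2)
            p_in = 1.0
        prob = np.where(arch == target, p_in, background_rate)
        hit = rng.random(len(dhs)) < prob
        presence[tf] = hit
        for i in np.flatnonzero(hit):
            d = dhs.iloc[i]
            off = int(rng.integers(0, d.end - d.start - hit_width))
            match_p = 10.0 ** rng.uniform(-8, np.log10(p_ceiling) - 0.01)
            rows.append(
                (f"{tf}_motif", tf, d.chrom, d.start + off, d.start + off + hit_width,
                 "+" if rng.random() < 0.5 else "-", match_p)
            )
    hits = pd.DataFrame(
        rows, columns=["motif_id", "tf", "chrom", "start", "end", "strand", "p_value"]
    )
    hits = sort_intervals(hits) if len(hits) else hits
    truth.motif_truth = pd.DataFrame(presence, index=dhs["dhs_id"].to_numpy())
    return hits


def simulate_orthology(truth: SimTruth, proportions: dict, seed: int = 0):
    """Assign shared/diverged/unalignable categories in exact proportion and
    build the matching orthology map and partner-species DHS set.

    Returns (ortho_map, partner_dhs) DataFrames; categories are stored on
    truth.orthology_truth. Shared DHSs map to a partner interval containing a
    partner DHS; diverged map to an interval with none; unalignable get no
    mapping.
    """
    cats = ("shared", "diverged", "unalignable")
    if set(proportions) != set(cats):
        raise ValueError(f"proportions must cover {cats}")
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed % (2**31))
    dhs = truth.true_dhs
    counts = largest_remainder_counts(len(dhs), [proportions[c] for c in cats])
    labels = np.repeat(cats, counts)
    rng.shuffle(labels)
    truth.orthology_truth = pd.Series(labels, index=dhs["dhs_id"].to_numpy(), name="category")

    map_rows, partner_rows = [], []
    for (row, cat) in zip(dhs.itertuples(index=False), labels):
        if cat == "unalignable":
            continue
        tgt_chrom = "p" + row.chrom
        map_rows.append((row.chrom, row.start, row.end, tgt_chrom, row.start, row.end))
        if cat == "shared":
            partner_rows.append((tgt_chrom, row.start, row.end))
    ortho_map = pd.DataFrame(
        map_rows,
        columns=["src_chrom", "src_start", "src_end", "tgt_chrom", "tgt_start", "tgt_end"],
    )
    partner = pd.DataFrame(partner_rows, columns=["chrom", "start", "end"])
    return ortho_map, partner
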
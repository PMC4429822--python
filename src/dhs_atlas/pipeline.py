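"""End-to-end orchestration: tags -> hotspots/peaks -> master list ->
temporal clustering -> annotation -> motif enrichment -> conservation.

`run_all` executes the full analysis on a synthetic three-stage design (or
on tag files listed in a manifest), writes every intermediate artifact to
the output directory, and returns a machine-readable report. Identical
config + seed reproduces an identical report body.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas, clustering, conservation, hotspots, motifs, simulate, util

log = logging.getLogger("dhs_atlas")


@dataclass
class RunConfig:
    """All fixed constants of a pipeline run, with the field's defaults."""

    target_depth: int = 1_000_000  # full-scale runs use 25_000_000
    fdr_target: float = 0.01
    window: int = 150
    step: int = 20
    k: int = 12
    occupancy_overlap: int = 75
    mapping_overlap: int = 25
    promoter_upstream: int = 1_000
    motif_p: float = 1e-4
    alpha: float = 0.01
    n_null_replicates: int = 3
    seed: int = 0
    # synthetic design
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_true_dhs: int = 2_000
    dhs_width: int = 200
    enrichment_fold: float = 10.0
    stages: tuple = ("P0", "P7", "Adult")
    chip_overlap_fraction: float = 0.8
    chip_n_peaks: int = 200
    motif_background_rate: float = 0.05
    motif_odds: float = 20.0
    orthology_proportions: dict = field(
        default_factory=lambda: {"shared": 0.6, "diverged": 0.3, "unalignable": 0.1}
    )
    manifest: list = field(default_factory=list)  # (sample_id, stage, tag BED path)

    def validate(self) -> None:
        for name in (
            "target_depth", "window", "step", "k", "occupancy_overlap",
            "mapping_overlap", "promoter_upstream",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr_target < 1:
            raise ValueError("fdr_target must be in (0, 1)")

    def sim_config(self) -> simulate.SimConfig:
        return simulate.SimConfig(
            n_chroms=self.n_chroms,
            chrom_length=self.chrom_length,
            n_true_dhs=self.n_true_dhs,
            dhs_width=self.dhs_width,
            enrichment_fold=self.enrichment_fold,
            depth=self.target_depth,
            stages=tuple(self.stages),
            seed=self.seed,
        )

    def hash(self) -> str:
        d = asdict(self)
        d["orthology_proportions"] = sorted(d["orthology_proportions"].items())
        d["manifest"] = list(map(tuple, d["manifest"]))
        return util.config_hash({k: str(v) for k, v in d.items()})


def _load_manifest_tags(config: RunConfig) -> dict:
    tagsets = {}
    genome = {f"chr{i+1}": config.chrom_length for i in range(config.n_chroms)}
    for sample_id, stage, path in config.manifest:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"manifest tag file missing: {p}")
        bed = util.read_bed(p)
        tags = pd.DataFrame(
            {"chrom": bed["chrom"], "pos": bed["start"], "strand": bed.get("strand", "+")}
        ).sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        tagsets[stage] = hotspots.TagSet(sample_id, tags, genome)
    return tagsets


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and write all artifacts under outdir."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    chash = config.hash()
    report: dict = {"config_hash": chash, "seed": config.seed, "samples": {}}

    stage_name = "simulate"
    try:
        sim_cfg = config.sim_config()
        truth = simulate.simulate_truth(sim_cfg)
        if config.manifest:
            tagsets = _load_manifest_tags(config)
        else:
            tagsets = {}
            for stage in config.stages:
                ts, _ = simulate.simulate_tags(sim_cfg, stage, truth=truth)
                tagsets[stage] = ts
        mappable = pd.DataFrame(
            [(c, 0, l) for c, l in sim_cfg.genome.items()],
            columns=["chrom", "start", "end"],
        )
        util.write_tsv(truth.true_dhs, outdir / "true_dhs.tsv")

        stage_name = "hotspots"
        peak_sets, tracks_by_sample, spots = {}, {}, {}
        for stage, ts in tagsets.items():
            cal = hotspots.calibrate_threshold(
                ts, mappable, target_fdr=config.fdr_target,
                seed=config.seed + 11 * (list(tagsets).index(stage) + 1),
                n_replicates=config.n_null_replicates,
            )
            tracks = hotspots.count_cuts(ts, config.window, config.step)
            hs = hotspots.call_hotspots(tracks, cal.threshold)
            peaks = hotspots.call_peaks(hs, tracks)
            spot = hotspots.spot_score(ts, hs)
            peak_sets[stage] = peaks
            tracks_by_sample[stage] = tracks
            spots[stage] = spot
            util.write_bed(hs[["chrom", "start", "end"]], outdir / f"hotspots_{stage}.bed")
            util.write_bed(peaks[["chrom", "start", "end"]], outdir / f"peaks_{stage}.bed")
            report["samples"][stage] = {
                "spot": round(spot, 4),
                "n_hotspots": int(len(hs)),
                "n_peaks": int(len(peaks)),
                "threshold": cal.threshold,
                "fdr_estimate": cal.fdr_estimate,
            }
            log.info("stage %s: %d hotspots, SPOT %.3f (%.1fs)", stage, len(hs), spot, time.time() - t0)

        stage_name = "masterlist"
        master = atlas.build_master_list(peak_sets)
        util.write_tsv(master, outdir / "master_list.tsv")
        report["master_size"] = int(len(master))

        stage_name = "clustering"
        raw = atlas.max_density_per_sample(master, tracks_by_sample)
        mat = clustering.normalize(raw, spots)
        model = clustering.kmeans_cluster(mat, k=config.k, seed=config.seed)
        util.write_tsv(
            pd.DataFrame(
                {
                    "dhs_id": model.assignments.index,
                    "cluster": model.assignments.to_numpy(),
                    "label": [model.labels[c] for c in model.assignments.to_numpy()],
                }
            ),
            outdir / "clusters.tsv",
        )
        report["cluster_sizes"] = {
            int(c): int(n) for c, n in model.assignments.value_counts().sort_index().items()
        }
        report["cluster_labels"] = {int(c): l for c, l in model.labels.items()}

        stage_name = "annotation"
        promoter = atlas.classify_promoter(master, truth.tss, config.promoter_upstream)
        chip = simulate.simulate_chip_peaks(
            truth, config.chip_overlap_fraction, config.chip_n_peaks,
            seed=config.seed + 101, factor="TF1",
        )
        occ_calls, per_peak, tally = atlas.occupancy(
            master, chip, factor="TF1", min_overlap=config.occupancy_overlap
        )
        summary = clustering.cluster_summary(
            model, mat, promoter, {"TF1": (per_peak, tally["total_peaks"])}
        )
        util.write_tsv(summary, outdir / "cluster_summary.tsv")
        report["occupancy"] = tally

        stage_name = "enrichment"
        arch_of = dict(zip(truth.true_dhs["dhs_id"], truth.true_dhs["archetype"]))
        tf_enrichment = {
            "TF_early": ("early", config.motif_odds),
            "TF_late": ("late", config.motif_odds),
            "TF_null": ("mid", 1.0),
        }
        hits = simulate.simulate_motif_hits(
            truth, tf_enrichment, config.motif_background_rate, seed=config.seed + 202
        )
        # project hits onto the called master list
        presence, _ = motifs.dhs_motif_presence(master, hits, config.motif_p)
        records = []
        for cl in range(model.k):
            ids = model.assignments.index[model.assignments == cl]
            records.append(
                motifs.hypergeom_enrichment(ids, presence, cluster_label=str(cl))
            )
        rec = motifs.bonferroni(pd.concat(records, ignore_index=True), alpha=config.alpha)
        util.write_tsv(rec, outdir / "enrichment.tsv")
        util.write_tsv(motifs.enrichment_matrix(rec), outdir / "enrichment_matrix.tsv", index=True)
        top = rec.sort_values("p").head(5)
        report["top_enrichments"] = [
            {"tf": r.tf, "cluster": r.cluster, "p_bonf": float(r.p_bonf)}
            for r in top.itertuples(index=False)
        ]

        stage_name = "conservation"
        ortho_map, partner = simulate.simulate_orthology(
            truth, config.orthology_proportions, seed=config.seed + 303
        )
        cons = conservation.categorize(
            truth.true_dhs, ortho_map, partner, min_overlap=config.mapping_overlap
        )
        table, props = conservation.category_distribution({"retina": cons})
        util.write_tsv(table, outdir / "conservation_counts.tsv", index=True)
        report["conservation"] = {
            c: int(table.loc["retina", c]) for c in table.columns
        }
    except Exception as exc:
        log.error("pipeline aborted in stage %r: %s", stage_name, exc)
        raise RuntimeError(f"pipeline aborted in stage {stage_name!r}: {exc}") from exc

    report["runtime_s"] = round(time.time() - t0, 2)
    body = {k: v for k, v in report.items() if k != "runtime_s"}
    (outdir / "report.json").write_text(
        json.dumps({**body, "runtime_s": report["runtime_s"]}, indent=2, sort_keys=True)
    )
    report["_truth"] = truth
    report["_model"] = model
    report["_master"] = master
    report["_conservation_records"] = cons
    report["_enrichment"] = rec
    return report


def validate_against_truth(report: dict, truth: simulate.SimTruth, outdir: str | Path | None = None) -> dict:
    """Compare a synthetic run's outputs with its planted ground truth.

    Returns hotspot sensitivity and empirical FDR vs planted DHSs, cluster
    purity vs archetypes, recovery of planted enriched TFs, and the
    conservation category exact-match rate.
    """
    master: pd.DataFrame = report["_master"]
    model = report["_model"]
    metrics: dict = {}

    # hotspot-level: master list vs planted DHSs
    n_hits, _, best = atlas.overlap_stats(
        master, atlas.sort_intervals(truth.true_dhs[["chrom", "start", "end"]])
    )
    called_true = n_hits > 0
    metrics["master_fdr"] = float(1.0 - called_true.mean()) if len(master) else 1.0
    recovered = set(best[called_true])
    metrics["dhs_sensitivity"] = len(recovered) / len(truth.true_dhs)

    # cluster purity vs archetypes (only master DHSs matching one true DHS)
    arch = truth.true_dhs["archetype"].to_numpy()
    ok = np.flatnonzero(called_true)
    if len(ok):
        assign = model.assignments.iloc[ok].to_numpy()
        labels = arch[best[ok]]
        df = pd.DataFrame({"cluster": assign, "arch": labels})
        purity = df.groupby("cluster")["arch"].agg(lambda s: s.value_counts().iloc[0]).sum() / len(df)
        metrics["cluster_purity"] = float(purity)
    # enrichment recovery of planted TFs
    rec = report.get("_enrichment")
    if rec is not None:
        planted = [tf for tf in rec["tf"].unique() if not tf.endswith("_null")]
        metrics["enrichment_recovered"] = {
            tf: bool(rec.loc[rec["tf"] == tf, "significant"].any()) for tf in planted
        }
    cons = report.get("_conservation_records")
    if cons is not None and truth.orthology_truth is not None:
        match = (
            cons.set_index("dhs_id")["category"]
            .reindex(truth.orthology_truth.index)
            .eq(truth.orthology_truth)
        )
        metrics["conservation_match_rate"] = float(match.mean())
    return metrics
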
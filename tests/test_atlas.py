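"""Master list construction and interval classification rules."""

import numpy as np
import pandas as pd
import pytest

from dhs_atlas import atlas


def iv(*rows):
    return pd.DataFrame(list(rows), columns=["chrom", "start", "end"])


class TestMasterList:
    def test_identical_sets_reproduce_input(self):
        a = iv(("chr1", 100, 250), ("chr1", 500, 700))
        m = atlas.build_master_list({"A": a, "B": a.copy()})
        assert list(zip(m["start"], m["end"])) == [(100, 250), (500, 700)]
        assert (m["source_samples"] == "A,B").all()

    def test_overlapping_pair_merges_to_union(self):
        m = atlas.build_master_list(
            {"A": iv(("chr1", 100, 250)), "B": iv(("chr1", 200, 350))}
        )
        assert len(m) == 1
        assert (m.loc[0, "start"], m.loc[0, "end"]) == (100, 350)

    def test_chain_merges_transitively(self):
        peaks = iv(*[("chr1", s, s + 150) for s in (0, 100, 200, 300, 400)])
        m = atlas.build_master_list({"A": peaks.iloc[::2], "B": peaks.iloc[1::2]})
        assert len(m) == 1
        assert (m.loc[0, "start"], m.loc[0, "end"]) == (0, 550)

    def test_abutting_intervals_not_merged(self):
        m = atlas.build_master_list(
            {"A": iv(("chr1", 0, 150)), "B": iv(("chr1", 150, 300))}
        )
        assert len(m) == 2

    def test_centroid_mode_fixed_width(self):
        m = atlas.build_master_list(
            {"A": iv(("chr1", 100, 250)), "B": iv(("chr1", 200, 350))},
            representative="centroid150",
        )
        assert len(m) == 1
        assert m.loc[0, "end"] - m.loc[0, "start"] == 150
        assert m.loc[0, "start"] == (100 + 350) // 2 - 75

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        s = np.sort(rng.integers(0, 100_000, 200))
        peaks = iv(*[("chr1", int(x), int(x) + 150) for x in s])
        m1 = atlas.build_master_list({"A": peaks})
        m2 = atlas.build_master_list({"A": m1[["chrom", "start", "end"]]})
        assert m1[["chrom", "start", "end"]].equals(m2[["chrom", "start", "end"]])
        e = m1["end"].to_numpy()
        assert (m1["start"].to_numpy()[1:] >= e[:-1]).all()


class TestMaxDensity:
    def test_max_over_intersecting_windows(self):
        from dhs_atlas.hotspots import CutWindowTrack

        counts = np.zeros(100, dtype=np.int32)
        counts[10], counts[11], counts[12] = 31, 72, 50  # densities x10 at 1e5 tags
        track = CutWindowTrack("chr1", 150, 20, counts, total_tags=100_000, chrom_length=5_000)
        master = pd.DataFrame(
            {"dhs_id": ["d1", "d2"], "chrom": "chr1", "start": [200, 4_000], "end": [300, 4_100]}
        )
        mat = atlas.max_density_per_sample(master, {"s": {"chr1": track}})
        # windows 10,11,12 (starts 200,220,240) all intersect [200,300)
        assert mat.loc["d1", "s"] == pytest.approx(72 * 10.0)
        assert mat.loc["d2", "s"] == 0.0


class TestPromoter:
    tss = pd.DataFrame(
        {"gene": ["g1"], "chrom": ["chr1"], "position": [50_000], "strand": ["+"]}
    )

    def _master(self, start, end):
        return pd.DataFrame(
            {"dhs_id": ["d"], "chrom": ["chr1"], "start": [start], "end": [end]}
        )

    def test_upstream_dhs_is_promoter(self):
        assert atlas.classify_promoter(self._master(49_500, 49_650), self.tss).all()

    def test_downstream_dhs_is_not(self):
        assert not atlas.classify_promoter(self._master(50_010, 50_160), self.tss).any()

    def test_boundary_at_minus_1kb_included(self):
        assert atlas.classify_promoter(self._master(49_000, 49_001), self.tss).all()
        assert not atlas.classify_promoter(self._master(48_999, 49_000), self.tss).any()

    def test_minus_strand_upstream_is_downstream_in_coords(self):
        tss = self.tss.assign(strand="-")
        assert atlas.classify_promoter(self._master(50_500, 50_600), tss).all()
        assert not atlas.classify_promoter(self._master(49_500, 49_650), tss).any()


class TestPartition:
    def test_precedence_and_construction_proportions(self):
        """Planted composition (promoter/exon/intron/intergenic) is recovered."""
        rng = np.random.default_rng(12)
        rows, truth = [], []
        tss_rows, exon_rows, intron_rows = [], [], []
        pos = 10_000
        for i in range(200):
            r = i % 10
            if r < 1:  # promoter: DHS just upstream of a TSS
                tss_rows.append(("g%d" % i, "chr1", pos + 600, "+"))
                rows.append(("chr1", pos, pos + 150))
                truth.append("promoter")
            elif r < 3:  # exon
                exon_rows.append(("chr1", pos - 50, pos + 300))
                rows.append(("chr1", pos, pos + 150))
                truth.append("exon")
            elif r < 7:  # intron
                intron_rows.append(("chr1", pos - 50, pos + 300))
                rows.append(("chr1", pos, pos + 150))
                truth.append("intron")
            else:  # distal intergenic (no TSS within 2.5 kb)
                rows.append(("chr1", pos, pos + 150))
                truth.append("distal_intergenic")
            pos += 10_000
        master = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        master.insert(0, "dhs_id", [f"d{i}" for i in range(len(master))])
        cats = atlas.genomic_partition(
            master,
            tss=pd.DataFrame(tss_rows, columns=["gene", "chrom", "position", "strand"]),
            exons=iv(*exon_rows),
            introns=iv(*intron_rows),
        )
        assert list(cats) == truth

    def test_promoter_beats_exon(self):
        master = pd.DataFrame(
            {"dhs_id": ["d"], "chrom": ["chr1"], "start": [900], "end": [1_050]}
        )
        tss = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"], "position": [1_100], "strand": ["+"]})
        cats = atlas.genomic_partition(master, tss=tss, exons=iv(("chr1", 800, 1_200)))
        assert cats.iloc[0] == "promoter"

    def test_missing_annotation_warns(self):
        master = pd.DataFrame({"dhs_id": ["d"], "chrom": ["chr1"], "start": [0], "end": [150]})
        with pytest.warns(UserWarning):
            cats = atlas.genomic_partition(master, tss=None, exons=None, introns=None)
        assert cats.iloc[0] == "distal_intergenic"


class TestOccupancy:
    master = pd.DataFrame(
        {"dhs_id": ["d1", "d2"], "chrom": "chr1", "start": [1_000, 1_200], "end": [1_150, 1_350]}
    )

    def test_70bp_overlap_unoccupied(self):
        calls, _, tally = atlas.occupancy(self.master.iloc[:1], iv(("chr1", 1_080, 1_300)))
        assert (calls["status"] == "unoccupied").all()
        assert tally["non_overlapping"] == 1

    def test_100bp_overlap_occupied(self):
        calls, _, tally = atlas.occupancy(self.master.iloc[:1], iv(("chr1", 1_000, 1_100)))
        assert calls.set_index("dhs_id").loc["d1", "status"] == "occupied"
        assert tally["occupying_peaks"] == 1

    def test_straddling_peak_excluded(self):
        # peak [1050,1300) overlaps d1 by 100 and d2 by 100
        calls, _, tally = atlas.occupancy(self.master, iv(("chr1", 1_050, 1_300)))
        assert tally["multi_overlap_excluded"] == 1
        assert (calls["status"] == "unoccupied").all()

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(5)
        ms = np.arange(0, 400_000, 400)
        master = pd.DataFrame(
            {"dhs_id": [f"d{i}" for i in range(len(ms))], "chrom": "chr1",
             "start": ms, "end": ms + rng.integers(100, 300, len(ms))}
        )
        ps = np.sort(rng.choice(400_000, 500, replace=False))
        peaks = iv(*[("chr1", int(p), int(p) + 150) for p in ps])
        calls, per_peak, tally = atlas.occupancy(master, peaks)
        # brute force
        occupied = set()
        n_multi = n_none = 0
        for _, pk in peaks.iterrows():
            hits = []
            for _, d in master.iterrows():
                ov = min(pk["end"], d["end"]) - max(pk["start"], d["start"])
                if ov >= 75:
                    hits.append(d["dhs_id"])
            if len(hits) == 0:
                n_none += 1
            elif len(hits) == 1:
                occupied.add(hits[0])
            else:
                n_multi += 1
        got = set(calls.loc[calls["status"] == "occupied", "dhs_id"])
        assert got == occupied
        assert tally["multi_overlap_excluded"] == n_multi
        assert tally["non_overlapping"] == n_none

    def test_order_invariance(self):
        peaks = iv(("chr1", 1_000, 1_100), ("chr1", 1_250, 1_400))
        a, _, _ = atlas.occupancy(self.master, peaks)
        b, _, _ = atlas.occupancy(self.master, peaks.iloc[::-1].reset_index(drop=True))
        assert a.equals(b)


class TestSubtractSpecific:
    def test_overlap_24_retained_25_removed(self):
        target = iv(("chr1", 1_000, 1_150), ("chr1", 2_000, 2_150))
        others = [iv(("chr1", 1_126, 1_300), ("chr1", 2_125, 2_300))]
        # overlaps: 24 bp with the first, 25 bp with the second
        out = atlas.subtract_specific(target, others, min_overlap=25)
        assert list(out["start"]) == [1_000]

    def test_planted_shared_unique_counts(self):
        shared = [("chr1", i * 1_000, i * 1_000 + 150) for i in range(600)]
        unique = [("chr1", 700_000 + i * 1_000, 700_000 + i * 1_000 + 150) for i in range(400)]
        target = iv(*(shared + unique))
        out = atlas.subtract_specific(target, [iv(*shared)], min_overlap=25)
        assert len(out) == 400

    def test_empty_others_warns_and_returns_target(self):
        target = iv(("chr1", 0, 150))
        with pytest.warns(UserWarning):
            out = atlas.subtract_specific(target, [])
        assert out.equals(target)


class TestOverlapMatrix:
    def test_identical_sets_full_overlap(self):
        a = iv(("chr1", 0, 150), ("chr1", 1_000, 1_150))
        mat, _, _ = atlas.pairwise_overlap_matrix({"A": a, "B": a.copy()})
        assert mat.loc["A", "B"] == 1.0
        assert mat.loc["A", "A"] == 1.0

    def test_partial_overlap_fraction(self):
        a = iv(*[("chr1", i * 1_000, i * 1_000 + 150) for i in range(100)])
        b = iv(*[("chr1", i * 1_000, i * 1_000 + 150) for i in range(80)])
        mat, _, _ = atlas.pairwise_overlap_matrix({"A": a, "B": b})
        assert mat.loc["A", "B"] == pytest.approx(0.80)
        assert mat.loc["B", "A"] == pytest.approx(1.0)

    def test_dendrogram_joins_similar_pair_first(self):
        base = [("chr1", i * 1_000, i * 1_000 + 150) for i in range(100)]
        a = iv(*base)
        b = iv(*(base[:90] + [("chr2", i * 1_000, i * 1_000 + 150) for i in range(10)]))
        c = iv(*(base[:10] + [("chr3", i * 1_000, i * 1_000 + 150) for i in range(90)]))
        mat, Z, order = atlas.pairwise_overlap_matrix({"A": a, "B": b, "C": c})
        # first merge joins A and B (indices 0 and 1)
        assert sorted(Z[0, :2].astype(int).tolist()) == [0, 1]
        assert order.index("C") in (0, 2)

    def test_empty_set_excluded_with_warning(self):
        a = iv(("chr1", 0, 150))
        with pytest.warns(UserWarning):
            mat, Z, order = atlas.pairwise_overlap_matrix(
                {"A": a, "B": a.copy(), "E": iv()}
            )
        assert (mat.loc["E"] == [0, 0, 1]).all() or mat.loc["E", "E"] == 1.0
        assert "E" not in order
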
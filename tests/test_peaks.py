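"""Shuffle-FDR peak calling, interval algebra and gene association."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from damidreg.genome import GeneAnnotation, GenomeModel
from damidreg.occupancy import OccupancyTrack
from damidreg.peaks import (
    PeakSet,
    call_peaks_fdr,
    compare_occupancy,
    intersect_replicate_peaks,
    merge_intervals,
    peaks_to_genes,
)


def mask_from_intervals(df, length=2000):
    mask = {}
    for chrom, sub in df.groupby("chrom"):
        m = np.zeros(length, dtype=bool)
        for s, e in zip(sub["start"], sub["end"]):
            m[s:e] = True
        mask[chrom] = m
    return mask


def intervals_from_mask(mask):
    rows = []
    for chrom, m in mask.items():
        padded = np.concatenate(([False], m, [False])).astype(np.int8)
        d = np.diff(padded)
        for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


def random_intervals(rng, n, length=2000, chroms=("c1", "c2")):
    rows = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(length, s + 60) + 1))
        rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestCallPeaks:
    def test_constant_track_yields_no_peaks(self, unit_fragmap):
        track = OccupancyTrack("CD", np.zeros(1000), unit_fragmap)
        assert len(call_peaks_fdr(track, seed=0)) == 0

    def test_planted_run_is_the_single_peak(self, unit_fragmap):
        rng = np.random.default_rng(123)
        values = rng.normal(0, 1, 1000)
        values[400:420] = 5.0
        track = OccupancyTrack("CD", values, unit_fragmap)
        ps = call_peaks_fdr(track, fdr_max=0.01, n_shuffles=100, seed=5)
        assert len(ps) == 1
        peak = ps.peaks.iloc[0]
        assert peak["start"] <= 400 and peak["end"] >= 420
        assert peak["n_fragments"] >= 20

    def test_null_calibration_rarely_calls_peaks(self, unit_fragmap):
        # a permuted (exchangeable) track should essentially never give a peak
        n_with_peaks = 0
        for seed in range(25):
            rng = np.random.default_rng(1000 + seed)
            track = OccupancyTrack("CD", rng.normal(0, 1, 1000), unit_fragmap)
            if len(call_peaks_fdr(track, fdr_max=0.01, n_shuffles=50, seed=seed)) > 0:
                n_with_peaks += 1
        assert n_with_peaks <= 2

    def test_fdr_monotone_in_run_length(self, unit_fragmap):
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, 1000)
        values[100:130] = 4.0
        values[600:604] = 4.0
        track = OccupancyTrack("CD", values, unit_fragmap)
        ps = call_peaks_fdr(track, fdr_max=1.1, n_shuffles=50, seed=2)
        df = ps.peaks.sort_values("n_fragments")
        fdrs = df["fdr"].to_numpy()
        assert np.all(np.diff(fdrs) <= 1e-12)

    def test_too_few_fragments_rejected(self):
        from damidreg.fragments import GATCFragmentMap

        fm = GATCFragmentMap(["c"], {"c": 10}, {"c": np.arange(0, 11, dtype=np.int64)})
        track = OccupancyTrack("CD", np.zeros(10), fm)
        with pytest.raises(ValueError):
            call_peaks_fdr(track, min_run=2)


class TestMergeIntersect:
    def test_overlapping_merge(self):
        df = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 5], "end": [10, 20]})
        out = merge_intervals(df)
        assert out.values.tolist() == [["c", 0, 20]]

    def test_bookended_merge(self):
        df = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 10], "end": [10, 20]})
        out = merge_intervals(df)
        assert out.values.tolist() == [["c", 0, 20]]

    def test_malformed_interval_rejected(self):
        df = pd.DataFrame({"chrom": ["c"], "start": [10], "end": [10]})
        with pytest.raises(ValueError):
            merge_intervals(df)

    def test_merge_matches_mask_union_oracle(self):
        rng = np.random.default_rng(3)
        df = random_intervals(rng, 1000)
        merged = merge_intervals(df)
        expected = intervals_from_mask(mask_from_intervals(df))
        pd.testing.assert_frame_equal(merged.reset_index(drop=True), expected)

    def test_intersection_idempotent_and_disjoint(self):
        a = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]}))
        same = intersect_replicate_peaks([a, a])
        assert same.intervals().values.tolist() == [["c", 0, 10]]
        b = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [20], "end": [30]}))
        assert len(intersect_replicate_peaks([a, b])) == 0

    def test_intersection_matches_mask_oracle(self):
        rng = np.random.default_rng(4)
        sets = [PeakSet(random_intervals(rng, 200)) for _ in range(3)]
        got = intersect_replicate_peaks(sets).intervals()
        masks = [mask_from_intervals(merge_intervals(s.intervals())) for s in sets]
        chroms = set().union(*(m.keys() for m in masks))
        inter = {
            c: np.logical_and.reduce([m.get(c, np.zeros(2000, bool)) for m in masks])
            for c in chroms
        }
        expected = intervals_from_mask(inter)
        pd.testing.assert_frame_equal(got.reset_index(drop=True), expected)

    def test_single_set_rejected(self):
        a = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]}))
        with pytest.raises(ValueError):
            intersect_replicate_peaks([a])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=30))
    def test_merge_output_sorted_disjoint(self, pairs):
        df = pd.DataFrame(
            [("c", s, s + l) for s, l in pairs], columns=["chrom", "start", "end"]
        )
        out = merge_intervals(df)
        assert (out["start"] < out["end"]).all()
        # strictly separated: no overlap, no bookending left unmerged
        assert (out["start"].iloc[1:].to_numpy() > out["end"].iloc[:-1].to_numpy()).all()


class TestPeaksToGenes:
    @pytest.fixture
    def annotated_genome(self):
        genes = [
            GeneAnnotation("gplus", "c", "+", 10_000, 12_000, 10_000),
            GeneAnnotation("gminus", "c", "-", 30_000, 32_000, 32_000),
        ]
        return GenomeModel(chromosomes=[("c", 50_000, "A" * 50_000)], genes=genes)

    def test_peak_in_gene_body_binds(self, annotated_genome):
        ps = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [11_000], "end": [11_200]}))
        out = peaks_to_genes(ps, annotated_genome).set_index("gene_id")
        assert bool(out.loc["gplus", "bound"])

    def test_upstream_window_rule(self, annotated_genome):
        near = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [8_400], "end": [8_600]}))
        far = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [7_400], "end": [7_600]}))
        out_near = peaks_to_genes(near, annotated_genome).set_index("gene_id")
        out_far = peaks_to_genes(far, annotated_genome).set_index("gene_id")
        assert bool(out_near.loc["gplus", "bound"])       # 1.5 kb upstream
        assert not bool(out_far.loc["gplus", "bound"])    # 2.5 kb upstream

    def test_minus_strand_window_extends_right(self, annotated_genome):
        ps = PeakSet(pd.DataFrame({"chrom": ["c"], "start": [33_500], "end": [33_600]}))
        out = peaks_to_genes(ps, annotated_genome).set_index("gene_id")
        assert bool(out.loc["gminus", "bound"])

    def test_matches_bruteforce_overlap(self):
        rng = np.random.default_rng(6)
        genes = []
        for i in range(30):
            s = int(rng.integers(3000, 90_000))
            e = s + int(rng.integers(500, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            orf = s if strand == "+" else e
            genes.append(GeneAnnotation(f"g{i}", "c", strand, s, e, orf))
        genome = GenomeModel(chromosomes=[("c", 100_000, "A" * 100_000)], genes=genes)
        ps = PeakSet(random_intervals(rng, 60, length=99_000, chroms=("c",)))
        out = peaks_to_genes(ps, genome, upstream=2000).set_index("gene_id")
        for g in genes:
            if g.strand == "+":
                lo, hi = min(g.start, g.orf_start - 2000), g.end
            else:
                lo, hi = g.start, max(g.end, g.orf_start + 2000)
            expected = any(
                (r.start < hi) and (r.end > lo) for r in ps.intervals().itertuples()
            )
            assert bool(out.loc[g.gene_id, "bound"]) == expected


class TestCompareOccupancy:
    def make_genome_and_tracks(self, values_cd, values_sd, unit_fragmap):
        genes = [GeneAnnotation("g0", "chr1", "+", 500, 700, 500)]
        genome = GenomeModel(chromosomes=[("chr1", 1000, "A" * 1000)], genes=genes)
        t_cd = OccupancyTrack("CD", values_cd, unit_fragmap)
        t_sd = OccupancyTrack("SD", values_sd, unit_fragmap)
        return genome, t_cd, t_sd

    def test_identical_tracks_all_unchanged(self, unit_fragmap):
        v = np.random.default_rng(0).normal(0, 1, 1000)
        genome, t_cd, t_sd = self.make_genome_and_tracks(v, v.copy(), unit_fragmap)
        out = compare_occupancy(t_cd, t_sd, genome)
        assert (out["delta"] == 0).all()
        assert (out["group"] == "unchanged").all()

    def test_negation_flips_deltas(self, unit_fragmap):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)
        genome, t_cd, t_sd = self.make_genome_and_tracks(a, b, unit_fragmap)
        d1 = compare_occupancy(t_cd, t_sd, genome)["delta"]
        genome, t_cd2, t_sd2 = self.make_genome_and_tracks(-a, -b, unit_fragmap)
        d2 = compare_occupancy(t_cd2, t_sd2, genome)["delta"]
        np.testing.assert_allclose(d1.to_numpy(), -d2.to_numpy(), atol=1e-12)

    def test_gained_peak_lands_in_group1(self, unit_fragmap):
        cd = np.zeros(1000)
        sd = np.zeros(1000)
        sd[450:700] = 2.0  # covers the gene+upstream window
        genome, t_cd, t_sd = self.make_genome_and_tracks(cd, sd, unit_fragmap)
        out = compare_occupancy(t_cd, t_sd, genome)
        assert out.loc[0, "group"] == "1"
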
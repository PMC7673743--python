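"""Generator determinism, planted structure, and statistical oracles."""
import numpy as np
import pytest

from damidreg.fragments import find_gatc_starts
from damidreg.simulate import (
    SimConfig,
    simulate_damid_counts,
    simulate_expression_tables,
    simulate_genome,
)
from damidreg.exprstats import l2fc_skewness


def small_config(**kw):
    base = dict(
        seed=5,
        n_chroms=2,
        chrom_length_bp=120_000,
        n_genes=40,
        n_peaks_shared=4,
        n_peaks_gained=2,
        n_peaks_lost=2,
        read_depth=200_000,
        regulon_size=8,
        regulon_core_size=6,
        n_accessible_genes=10,
        n_background_pres=30,
    )
    base.update(kw)
    return SimConfig(**base)


class TestGenome:
    def test_same_seed_byte_identical(self):
        g1, t1 = simulate_genome(small_config())
        g2, t2 = simulate_genome(small_config())
        for (n1, l1, s1), (n2, l2, s2) in zip(g1.chromosomes, g2.chromosomes):
            assert (n1, l1) == (n2, l2) and s1 == s2
        assert t1.true_l2fc == t2.true_l2fc
        assert t1.tf_thresholds == t2.tf_thresholds
        for cond in ("CD", "SD"):
            assert t1.planted_peaks[cond].equals(t2.planted_peaks[cond])

    def test_zero_gatc_rate_means_no_sites(self):
        g, _ = simulate_genome(small_config(gatc_rate=0.0))
        for _, _, seq in g.chromosomes:
            assert len(find_gatc_starts(seq)) == 0

    def test_gatc_count_matches_binomial_oracle(self):
        cfg = small_config()
        g, _ = simulate_genome(cfg)
        expected = cfg.chrom_length_bp * cfg.gatc_rate
        for _, _, seq in g.chromosomes:
            observed = len(find_gatc_starts(seq))
            assert abs(observed - expected) <= 3 * np.sqrt(expected)

    def test_genes_non_overlapping_within_bounds(self):
        g, _ = simulate_genome(small_config())
        for chrom in g.chrom_names:
            spans = sorted(
                (x.start, x.end) for x in g.genes if x.chrom == chrom
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_states_tile_without_overlap(self):
        g, _ = simulate_genome(small_config())
        for chrom in g.chrom_names:
            sub = g.chromatin_states[g.chromatin_states["chrom"] == chrom].sort_values("start")
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == g.chrom_lengths[chrom]
            assert (sub["end"].iloc[:-1].to_numpy() == sub["start"].iloc[1:].to_numpy()).all()

    def test_planted_peaks_on_fragment_boundaries(self):
        _, truth = simulate_genome(small_config())
        fm = truth.fragmap
        for cond in ("CD", "SD"):
            for row in truth.planted_peaks[cond].itertuples():
                b = fm.boundaries[row.chrom]
                assert row.start in b and row.end in b

    def test_oversized_request_raises(self):
        with pytest.raises(ValueError, match="too short"):
            simulate_genome(small_config(n_genes=400))

    def test_motif_planting_recoverable_by_scan(self):
        from damidreg.motifs import max_z_per_gene, promoter_windows, scan_motif

        cfg = small_config()
        g, truth = simulate_genome(cfg)
        windows = promoter_windows(g, cfg.promoter_width)
        for motif in truth.motifs:
            hits = scan_motif(g, motif, keep_top_frac=0.01)
            gene_z = max_z_per_gene(hits, windows)
            tau = truth.tf_thresholds[motif.tf_name]
            members = truth.true_regulons[motif.tf_name]
            assert all(gene_z[m] >= tau for m in members)


class TestCounts:
    def test_same_seed_identical_tracks(self):
        cfg = small_config()
        g, t = simulate_genome(cfg)
        a = simulate_damid_counts(g, t, cfg)
        b = simulate_damid_counts(g, t, cfg)
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k].counts, b[k].counts)

    def test_zero_peak_effect_null_case(self):
        cfg = small_config(peak_effect=0.0)
        g, t = simulate_genome(cfg)
        tracks = simulate_damid_counts(g, t, cfg)
        fusion = tracks["fusion_CD_r1"].counts.astype(float)
        dam = tracks["Dam_CD_r1"].counts.astype(float)
        frags = t.peak_fragments["CD"]
        diff = (fusion[frags] - dam[frags]).mean()
        se = np.sqrt(2 * dam[frags].mean() / len(frags))
        assert abs(diff) <= 4 * se

    def test_peak_ratio_matches_poisson_oracle(self):
        cfg = small_config(read_depth=2_000_000)
        g, t = simulate_genome(cfg)
        tracks = simulate_damid_counts(g, t, cfg)
        frags = t.peak_fragments["SD"]
        fusion = tracks["fusion_SD_r1"].counts[frags].astype(float)
        dam = tracks["Dam_SD_r1"].counts[frags].astype(float)
        ratio = fusion.sum() / dam.sum()
        target = 2.0 ** cfg.peak_effect
        # delta-method SE of the count-sum ratio under Poisson sampling
        se = target * np.sqrt(1 / fusion.sum() + 1 / dam.sum())
        assert abs(ratio - target) <= 3 * se

    def test_totals_match_expected_depth(self):
        cfg = small_config()
        g, t = simulate_genome(cfg)
        tracks = simulate_damid_counts(g, t, cfg)
        for k, tr in tracks.items():
            total = tr.counts.sum()
            if tr.construct == "Dam":
                assert abs(total - cfg.read_depth) <= 3 * np.sqrt(cfg.read_depth)
            else:
                # fusion inflated by the planted enrichment, never by more than
                # the in-peak mass times the multiplier
                assert cfg.read_depth - 3 * np.sqrt(cfg.read_depth) <= total
                assert total <= cfg.read_depth * (1 + 0.3)


class TestExpression:
    def test_symmetric_null_skewness(self):
        cfg = SimConfig(
            seed=9, n_chroms=2, chrom_length_bp=2_500_000, n_genes=2000,
            n_peaks_shared=0, n_peaks_gained=0, n_peaks_lost=0, n_tfs=0,
            regulon_size=0, frac_null=1.0, regulon_effect=0.0,
            n_background_pres=0, n_accessible_genes=0,
        )
        g, t = simulate_genome(cfg)
        de = simulate_expression_tables(g, t, cfg)["SD_vs_CD"]
        assert abs(l2fc_skewness(de["l2fc"]).skewness) <= 0.2

    def test_repression_scenario_negative_skew(self):
        # ~30% of genes carry the planted repression at effect -1
        cfg = SimConfig(seed=10)
        g, t = simulate_genome(cfg)
        de = simulate_expression_tables(g, t, cfg)["SD_vs_CD"]
        assert l2fc_skewness(de["l2fc"]).skewness < 0

    def test_zero_se_reproduces_truth(self):
        cfg = small_config(se_scale=0.0)
        g, t = simulate_genome(cfg)
        de = simulate_expression_tables(g, t, cfg)["SD_vs_CD"].set_index("gene_id")
        for gene, eff in t.true_l2fc.items():
            assert de.loc[gene, "l2fc"] == pytest.approx(eff)

    def test_determinism(self):
        cfg = small_config()
        g, t = simulate_genome(cfg)
        d1 = simulate_expression_tables(g, t, cfg)["SD_vs_CD"]
        d2 = simulate_expression_tables(g, t, cfg)["SD_vs_CD"]
        assert d1.equals(d2)
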
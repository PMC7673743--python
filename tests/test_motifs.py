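"""PWM scanning, robust z, promoter windows and regulon inference."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from damidreg.genome import GeneAnnotation, GenomeModel
from damidreg.motifs import (
    MotifModel,
    Regulon,
    build_regulon,
    max_z_per_gene,
    promoter_windows,
    regulon_overlap_tests,
    robust_z,
    scan_motif,
    threshold_curve,
)


class TestRobustZ:
    def test_median_maps_to_zero(self):
        z = robust_z([1, 2, 3, 4, 5])
        assert z[2] == 0

    def test_outlier_hand_oracle(self):
        z = robust_z([1, 2, 3, 4, 100])
        # median 3, MAD 1: z = 97 / 1.4826
        assert z[-1] == pytest.approx(97 / 1.4826, rel=1e-9)
        assert z[-1] == pytest.approx(65.43, abs=0.01)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        np.testing.assert_allclose(robust_z(x), robust_z(3.5 * x + 11.0), atol=1e-9)

    def test_zero_mad_rejected(self):
        with pytest.raises(ValueError):
            robust_z([1.0, 1.0, 1.0, 9.0])


class TestScan:
    def make_genome(self, seq):
        return GenomeModel(chromosomes=[("c", len(seq), seq)])

    def test_planted_site_scores_maximal(self):
        rng = np.random.default_rng(1)
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 3000)))
        site = "TTACGCAT"
        seq[1000:1008] = site
        genome = self.make_genome("".join(seq))
        probs = np.full((8, 4), (1 - 0.85) / 3)
        for j, b in enumerate(site):
            probs[j, "ACGT".index(b)] = 0.85
        motif = MotifModel.from_probabilities("tf", probs)
        hits = scan_motif(genome, motif, keep_top_frac=1.0)
        best = hits.loc[hits["score"].idxmax()]
        assert best["pos"] == 1000
        assert best["score"] == pytest.approx(motif.max_score())

    def test_uniform_pwm_constant_scores(self):
        genome = self.make_genome("ACGTACGTACGTACGT")
        motif = MotifModel.from_probabilities("flat", np.full((4, 4), 0.25))
        hits = scan_motif(genome, motif, keep_top_frac=1.0)
        np.testing.assert_allclose(hits["score"], 0.0, atol=1e-12)

    def test_scores_match_naive_oracle(self):
        rng = np.random.default_rng(2)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        genome = self.make_genome(seq)
        probs = rng.dirichlet(np.ones(4), size=6)
        motif = MotifModel.from_probabilities("tf", probs)
        hits = scan_motif(genome, motif, keep_top_frac=1.0)
        fwd = hits[hits["strand"] == "+"].set_index("pos")["score"]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rev = hits[hits["strand"] == "-"].set_index("pos")["score"]
        for pos in rng.integers(0, 2000 - 6, size=100):
            word = seq[pos : pos + 6]
            expected = sum(motif.pwm[j, "ACGT".index(b)] for j, b in enumerate(word))
            assert fwd[pos] == pytest.approx(expected, rel=1e-9)
            rc = "".join(comp[b] for b in reversed(word))
            expected_rc = sum(motif.pwm[j, "ACGT".index(b)] for j, b in enumerate(rc))
            assert rev[pos] == pytest.approx(expected_rc, rel=1e-9)

    def test_bad_alphabet_rejected(self):
        genome = self.make_genome("ACGTXXACGT")
        motif = MotifModel.from_probabilities("tf", np.full((2, 4), 0.25))
        with pytest.raises(ValueError):
            scan_motif(genome, motif, keep_top_frac=1.0)


class TestPromoterWindows:
    def make(self, strand, orf):
        g = GeneAnnotation("g", "c", strand, min(orf, 4000), max(orf, 6000), orf)
        genome = GenomeModel(chromosomes=[("c", 20_000, "A" * 20_000)], genes=[g])
        return promoter_windows(genome, width=2000).iloc[0]

    def test_plus_strand(self):
        w = self.make("+", 5000)
        assert (w["start"], w["end"]) == (3000, 5000)

    def test_minus_strand(self):
        w = self.make("-", 5000)
        assert (w["start"], w["end"]) == (5000, 7000)

    def test_clipped_at_chromosome_start(self):
        g = GeneAnnotation("g", "c", "+", 500, 900, 500)
        genome = GenomeModel(chromosomes=[("c", 20_000, "A" * 20_000)], genes=[g])
        w = promoter_windows(genome, width=2000).iloc[0]
        assert (w["start"], w["end"]) == (0, 500)


class TestRegulons:
    def make_hits(self):
        hits = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "pos": [100, 1100, 2100, 3100],
                "strand": ["+"] * 4,
                "score": [5.0, 6.0, 7.0, 8.0],
                "z": [1.0, 2.0, 3.0, 4.0],
            }
        )
        hits.attrs["tf_name"] = "tf"
        windows = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(4)],
                "chrom": ["c"] * 4,
                "start": [0, 1000, 2000, 3000],
                "end": [1000, 2000, 3000, 4000],
                "strand": ["+"] * 4,
            }
        )
        return hits, windows

    def test_minus_infinity_threshold_takes_all_hit_genes(self):
        hits, windows = self.make_hits()
        reg = build_regulon(hits, windows, -np.inf)
        assert reg.genes == {"g0", "g1", "g2", "g3"}

    def test_threshold_above_max_empty(self):
        hits, windows = self.make_hits()
        assert build_regulon(hits, windows, 10.0).genes == set()

    def test_monotone_in_threshold(self):
        hits, windows = self.make_hits()
        r1 = build_regulon(hits, windows, 1.5).genes
        r2 = build_regulon(hits, windows, 3.5).genes
        assert r2 <= r1

    def test_recovery_on_synthetic_genome(self, small_sim):
        cfg, genome, truth = small_sim
        windows = promoter_windows(genome, cfg.promoter_width)
        for motif in truth.motifs:
            hits = scan_motif(genome, motif, keep_top_frac=0.01)
            reg = build_regulon(hits, windows, truth.tf_thresholds[motif.tf_name])
            truth_set = truth.true_regulons[motif.tf_name]
            jac = len(reg.genes & truth_set) / len(reg.genes | truth_set)
            assert jac >= 0.8


class TestThresholdCurve:
    def test_member_count_non_increasing(self, small_sim):
        cfg, genome, truth = small_sim
        from damidreg.simulate import simulate_expression_tables

        de = simulate_expression_tables(genome, truth, cfg)["SD_vs_CD"]
        windows = promoter_windows(genome, cfg.promoter_width)
        motif = truth.motifs[0]
        hits = scan_motif(genome, motif, keep_top_frac=0.01)
        curve = threshold_curve(hits, windows, de, np.arange(0.5, 12.1, 0.5), n_min=4)
        assert np.all(np.diff(curve.n_members) <= 0)
        assert curve.tau_star in curve.grid

    def test_all_empty_grid_rejected(self):
        hits = pd.DataFrame(
            {"chrom": ["c"], "pos": [10], "strand": ["+"], "score": [1.0], "z": [1.0]}
        )
        windows = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["c"], "start": [0], "end": [100], "strand": ["+"]}
        )
        de = pd.DataFrame({"gene_id": ["g"], "l2fc": [0.1]})
        with pytest.raises(ValueError):
            threshold_curve(hits, windows, de, [5.0, 6.0], n_min=1)


class TestOverlapTests:
    def make_regulons(self, overlap):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(30)}
        b = {f"g{i}" for i in range(30 - overlap, 70 - overlap)}
        return [Regulon("A", 0, a), Regulon("B", 0, b)], universe

    def test_independence_gives_unit_odds(self):
        regs, universe = self.make_regulons(12)
        res = regulon_overlap_tests(regs, universe)[0]
        assert (res.in_both, res.a_only, res.b_only, res.neither) == (12, 18, 28, 42)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_enriched_overlap_matches_hypergeometric_oracle(self):
        regs, universe = self.make_regulons(20)
        res = regulon_overlap_tests(regs, universe)[0]
        assert res.odds_ratio == pytest.approx(5.0)
        # two-sided Fisher p: sum of hypergeometric outcomes at most as likely
        rv = hypergeom(100, 30, 40)
        p0 = rv.pmf(20)
        expected = sum(rv.pmf(k) for k in range(0, 31) if rv.pmf(k) <= p0 * (1 + 1e-7))
        assert res.p == pytest.approx(expected, rel=1e-6)

    def test_identical_regulons_extreme(self):
        universe = {f"g{i}" for i in range(50)}
        a = {f"g{i}" for i in range(20)}
        regs = [Regulon("A", 0, a), Regulon("B", 0, set(a))]
        res = regulon_overlap_tests(regs, universe)[0]
        assert np.isinf(res.odds_ratio)
        assert res.p < 1e-10

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            regulon_overlap_tests([], set())
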
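"""Regulon inference: promoter PWM scans, threshold curves, overlaps.

For each transcription factor: scan the genome, convert scores to robust
z, trace the member-expression signal-to-noise across candidate z
thresholds, pick tau*, and build the regulon through the 2-kb upstream
window rule.  Reports recovery against the planted truth and the pairwise
Fisher overlap tests.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from damidreg.motifs import (
    build_regulon,
    promoter_windows,
    regulon_overlap_tests,
    scan_motif,
    threshold_curve,
)
from damidreg.pipeline import stage_seed
from damidreg.simulate import SimConfig, simulate_expression_tables, simulate_genome


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    cfg = SimConfig(seed=stage_seed(args.seed, "simulate"))
    genome, truth = simulate_genome(cfg)
    de = simulate_expression_tables(genome, truth, cfg)["SD_vs_CD"]
    windows = promoter_windows(genome, cfg.promoter_width)
    grid = np.arange(0.5, 15.01, 0.5)

    rows = []
    regulons = []
    for motif in truth.motifs:
        hits = scan_motif(genome, motif, keep_top_frac=0.01)
        curve = threshold_curve(hits, windows, de, grid)
        reg = build_regulon(hits, windows, curve.tau_star, tf_name=motif.tf_name)
        regulons.append(reg)
        t = truth.true_regulons[motif.tf_name]
        jac = len(reg.genes & t) / len(reg.genes | t)
        rows.append(
            {
                "tf": motif.tf_name,
                "tau_star": curve.tau_star,
                "tau_true": round(truth.tf_thresholds[motif.tf_name], 3),
                "n_members": len(reg.genes),
                "mean_member_l2fc": round(float(de.set_index("gene_id")["l2fc"]
                                                .reindex(sorted(reg.genes)).mean()), 3),
                "jaccard_vs_truth": round(jac, 3),
            }
        )
    df = pd.DataFrame(rows)
    print(df.to_string(index=False))

    universe = {g.gene_id for g in genome.genes}
    overlaps = regulon_overlap_tests(regulons, universe)
    odf = pd.DataFrame(
        [
            {"pair": f"{r.tf_a}|{r.tf_b}", "in_both": r.in_both,
             "odds_ratio": round(r.odds_ratio, 2), "p": f"{r.p:.2e}", "q": f"{r.q:.2e}"}
            for r in overlaps
        ]
    )
    print("\npairwise regulon overlaps (Fisher exact, BH-corrected):")
    print(odf.to_string(index=False))

    changed = set(de.loc[de["q"] < 0.1, "gene_id"])
    union = set().union(*(r.genes for r in regulons))
    cov = len(union & changed) / len(changed)
    print(f"\nregulon union covers {100*cov:.0f}% of diet-changed genes "
          f"({len(union & changed)}/{len(changed)})")

    res = Path(args.results)
    res.mkdir(parents=True, exist_ok=True)
    df.to_csv(res / "05_regulons.tsv", sep="\t", index=False)
    odf.to_csv(res / "05_regulon_overlaps.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
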
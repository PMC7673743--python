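"""Build the synthetic study: genome, annotations, counts, DE tables.

Writes a compact summary of the planted structure to results/, and the
full artifact set (FASTA/GFF3/BED/TSV) to scratch/artifacts/ for browsing.
"""
import argparse
import json
from pathlib import Path

from damidreg.pipeline import stage_seed
from damidreg.simulate import (
    SimConfig,
    simulate_damid_counts,
    simulate_expression_tables,
    simulate_genome,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--results", default="results")
    ap.add_argument("--artifacts", default="scratch/artifacts")
    args = ap.parse_args()

    cfg = SimConfig(seed=stage_seed(args.seed, "simulate"))
    genome, truth = simulate_genome(cfg)
    tracks = simulate_damid_counts(genome, truth, cfg)
    de = simulate_expression_tables(genome, truth, cfg)

    art = Path(args.artifacts)
    art.mkdir(parents=True, exist_ok=True)
    genome.write_fasta(art / "genome.fa")
    genome.write_gff3(art / "genes.gff3")
    genome.write_states_bed(art / "states.bed")
    genome.write_pres_bed(art / "pres.bed")
    (art / "counts").mkdir(exist_ok=True)
    for sid, tr in tracks.items():
        tr.to_frame().to_csv(art / "counts" / f"{sid}.tsv", sep="\t", index=False)
    (art / "de").mkdir(exist_ok=True)
    for name, df in de.items():
        df.to_csv(art / "de" / f"{name}.tsv", sep="\t", index=False)
    for tf, motif in zip(truth.tf_thresholds, truth.motifs):
        motif.write_tsv(art / f"pwm_{tf}.tsv")

    summary = {
        "seed": args.seed,
        "n_chromosomes": len(genome.chromosomes),
        "genome_bp": sum(L for _, L, _ in genome.chromosomes),
        "n_genes": len(genome.genes),
        "n_fragments": truth.fragmap.n_fragments,
        "planted_peaks": {c: int(len(truth.planted_peaks[c])) for c in ("CD", "SD")},
        "peak_categories": {k: len(v) for k, v in truth.peak_genes.items()},
        "n_pres": len(genome.pres),
        "regulon_sizes": {tf: len(g) for tf, g in truth.true_regulons.items()},
        "tf_thresholds_z": {tf: round(v, 3) for tf, v in truth.tf_thresholds.items()},
        "n_samples": len(tracks),
    }
    res = Path(args.results)
    res.mkdir(parents=True, exist_ok=True)
    with open(res / "01_simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))
    print(f"artifacts under {art}/, summary in {res}/01_simulation_summary.json")


if __name__ == "__main__":
    main()
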
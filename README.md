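# damidreg

Analysis pipeline for GATC-resolution DamID chromatin profiling and
transcription-factor regulon inference, exercised end to end on synthetic
genomes with planted ground truth.

The scientific setting is a Polycomb-biology study design: a Dam-fusion
construct (e.g. Dam::Pcl, marking PRC2.1 occupancy) and a Dam-only control
are profiled in a cell type of interest under two conditions — a control
diet (CD) and a sugar diet (SD). The analysis asks where the fusion
protein sits on chromatin, how its occupancy redistributes between
conditions, whether its binding sites coincide with predicted Polycomb
response elements (PREs) and Polycomb ("blue") chromatin, and whether a
small set of transcription factors whose promoters it binds can account —
through their regulons — for the repression signature seen in cell-type
specific expression data.

The package is aimed at computational biologists who want these
procedures as tested, reusable functions rather than one-off scripts, and
a generator that produces data with known truth to validate them against.

## What it computes

- **Occupancy** — reads or fragment counts are resolved on GATC fragments
  (the intervals between genomic GATC motifs, DamID's native resolution);
  the signal is `log2((cpm_fusion + ψ)/(cpm_Dam + ψ))` per fragment, and
  the Dam-only control doubles as a chromatin-accessibility read-out after
  1× genome coverage normalisation.
- **Peaks** — runs of ≥ `min_run` consecutive fragments above a track
  quantile threshold; significance by within-chromosome value shuffling:
  `FDR(n) = E_shuffle[#runs ≥ n] / observed[#runs ≥ n]`, peaks kept at
  FDR < 0.01 and intersected base-pair-wise across replicates.
- **Interval enrichment** — Monte Carlo permutation test: the peak set is
  re-placed uniformly per chromosome (length preserved, 1000 shuffles);
  fold = observed/null mean, `p = (1 + #{null ≥ obs}) / (1 + N)`.
- **Expression post-statistics** — moment skewness
  `m3 / m2^(3/2)` with denominator-n moments over all detected genes (a
  negative skew is the repression signature); a practical-equivalence
  (TOST) test that flags genes *significantly unchanged* by rejecting the
  composite null |θ| ≥ log2(1.5) using gene-wise SEs; BH FDR throughout.
- **Regulons** — every position of the genome is scored on both strands
  with each TF's PWM, scores become robust z
  (`(x − median)/(1.4826·MAD)`), and a gene joins a TF's regulon when a
  hit with z ≥ τ lies within 2 kb upstream of its ORF start. τ is read
  from a curve of `t(τ) = |mean l2fc| · √n / sd` over regulon members;
  pairwise regulon overlaps are tested with Fisher's exact test.
- **Synthetic data** — a generator plants all of the above (GATC
  structure, condition-specific occupancy peaks, PREs, five-colour
  chromatin states, motif sites, repressed regulons) so every step can be
  checked against known truth.

## Worked example

```bash
python analysis/06_full_pipeline.py --seed 1
```

runs the whole chain on the default synthetic study (2 chromosomes ×
500 kb, 400 genes, 5 TFs, 2 replicates/condition) and prints, among
others:

```
"recovery": {
  "peak_jaccard": {"CD": 1.0, "SD": 0.97},
  "regulon_jaccard_mean": 0.97,
  "tau_abs_error_mean": 0.045
},
"enrichment": {"all": 7.76, "intergenic": 10.82, "enhancer": 7.75},
"blue_state_ratio": 2.6,
"skewness_SD_vs_CD": -0.429
```

Reading: the peaks called at FDR < 0.01 coincide with the planted
occupancy peaks essentially base-for-base (Jaccard ≈ 1); the inferred
regulons match the planted ones (Jaccard 0.97) with the selected z
thresholds within 0.05 of the planted values; SD peaks are ~8-fold
enriched in high-confidence PREs; genes bound by the fusion protein sit
preferentially in Polycomb-blue chromatin (ratio 2.6, the maximum across
the five states); and the sugar-diet expression contrast shows the
planted negative l2fc skew. The numbered scripts `analysis/01…05` run the
stages individually and write their tables under `results/`.

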
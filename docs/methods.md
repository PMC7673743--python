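# Methods

## Occupancy model

DamID signal is intrinsically fragment-resolved: the methyltransferase
marks GATC sites, so the unit of observation is the GATC fragment — the
interval between consecutive GATC motif starts (the motif is its own
reverse complement; boundaries are placed at motif *start* coordinates,
an arbitrary but fixed convention since no base of the motif is
canonical). Fragments tile each chromosome exactly; a chromosome without
GATC is a single fragment.

Reads are assigned by extending each read 3′-ward from its start to
`min(start + 300 bp, nearest GATC boundary past the start)` and
incrementing every overlapped fragment — the extend-then-bin semantics of
standard DamID pipelines. Occupancy is
`log2((cpm_fusion + ψ)/(cpm_Dam + ψ))` with ψ = 1 on counts-per-million.
CPM makes the ratio depth-invariant; the pseudocount keeps empty
fragments finite. Replicates are ratioed separately and only averaged for
display, metaprofiles and per-gene condition comparisons. The Dam-only
(accessibility) track is normalised so that mean per-bp coverage over the
genome equals 1: `Σ value_i · length_i / genome_length = 1`.

## Peak calling

Peaks are maximal runs of at least `min_run = 2` consecutive fragments
strictly above a threshold taken as the `threshold_q = 0.95` quantile of
the track. The null distribution of run lengths comes from `n_shuffles =
100` permutations of the fragment values within each chromosome — the
simplest null that preserves both the value distribution and the fragment
structure. For each observed run length n,

    FDR(n) = mean_shuffles[# runs of length ≥ n] / observed[# runs ≥ n],

reported with monotone non-increase enforced in n (longer runs can only
be rarer under the null); runs with FDR < 0.01 become peaks on fragment
coordinates. On a permuted (exchangeable) track the observed and expected
run counts agree, FDR ≈ 1, and no peaks are called; the measured
false-positive rate over null tracks is ~0 per 30–50 seeds (see
`scripts/acceptance.py`). Replicate peak sets are combined by base-pair
intersection; overlapping or bookended intervals merge (mergeBed
semantics). A gene counts as bound when a peak touches its span extended
2 kb 5′ of the ORF start, strand-aware.

## Interval enrichment

Observed overlap = number of query intervals touching ≥ 1 bp of the
reference. The null re-places each query interval uniformly at random on
its own chromosome (length preserved, overlaps permitted, 1000 shuffles);
shuffling stays on the same chromosome to preserve chromosome
composition. Fold = observed / null mean;
`p = (1 + #{null ≥ observed}) / (1 + N)` (add-one rule, so p is never 0;
the depletion p is mirrored). PRE-class enrichment restricts the
reference to PREs of one class with prediction confidence ≥ 0.8.
Chromatin-state ratios assign each gene the five-colour state covering
its TSS and divide the bound-gene fraction per state by the genome-wide
fraction.

## Expression post-statistics

Skewness is `m3 / m2^{3/2}` with `m_r = Σ(x_i − μ)^r / n` — denominator-n
moments, no bias correction — computed over all detected genes
(`base_mean > 0`), not only significant ones. The practical-equivalence
test treats the composite null |θ| ≥ Δ with Δ = log2(1.5) by two
one-sided normal tests (TOST):
`p = max(Φ((l2fc − Δ)/se), Φ((−l2fc − Δ)/se))`; genes are *significantly
unchanged* at BH q < 0.1. At the null boundary the per-test rejection
rate is ≤ α (measured 2.9% at α = 5% over 10,000 simulated genes), and an
effect at or beyond the bound always has p ≥ 0.5 regardless of SE. BH
adjustment is applied over whatever gene subset the caller passes;
the subset choice is the caller's.

## Regulon inference

Each TF's PWM (log-odds vs. uniform background) is scored at every
position on both strands; N bases score as background (0). Scores are
converted to robust z with the genome-wide median and MAD (scale 1.4826
for normal consistency; a zero-MAD scan yields z = 0, carrying no
ranking). To bound memory only the top `keep_top_frac = 1%` of positions
are materialised as hits — the location/scale still come from all
positions, and the floor is configurable to 100%. A gene joins the
regulon at threshold τ when a hit with z ≥ τ lies in its promoter window
(2 kb upstream of the ORF start, strand-aware, clipped to the
chromosome). Regulons are monotone: raising τ can only shrink them.

The TF-specific τ* is chosen from the threshold curve: for each grid
point, members' mean l2fc, its SEM and `t(τ) = |mean|·√n/sd` are
recorded; τ* is the **centre of the plateau** of near-maximal t (within
0.1% of the maximum) among grid points with ≥ 20 members. Taking the
plateau centre rather than the first argmax is stable under grid
refinement and mimics choosing the point of maximum information content
relative to noise from the plotted curve; a per-TF override is available
for manual choices. Pairwise regulon overlaps use two-sided Fisher exact
tests over the full gene universe with BH correction.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with exact control over every planted feature:

- **Sequence.** I.i.d. uniform nucleotides; GATC motifs are planted at
  exponential-gap positions (rate `gatc_rate = 0.004`/bp, ~250 bp
  fragments, fly-like) and accidental GATC occurrences are mutated away,
  so the realised GATC set is exactly the planted one (and `gatc_rate=0`
  genomes have none).
- **Genes.** 400 genes in fixed-stride slots sized to hold a 2-kb
  promoter plus the gene body, so promoter windows never overlap
  neighbouring genes and planted motif sites are uniquely attributable.
  Real genomes have overlapping and nested promoters; this simplification
  means recovery results bound what is achievable on tidy promoters, not
  on dense loci.
- **Peaks.** 18 shared + 7 gained + 7 lost occupancy peaks per the ~70%
  between-condition sharing of the study design, each a run of 4–6
  consecutive fragments over a target gene's promoter; planted peaks lie
  on fragment boundaries by construction.
- **Counts.** Dam rates = lognormal per-fragment accessibility (σ = 0.5;
  ×4 at 100 designated accessible promoters) × fragment length, scaled to
  `read_depth = 10^6` expected reads; fusion rates multiply by
  `2^peak_effect` (peak_effect = 2) inside the planted peaks of the
  matching condition; counts are Poisson, two replicates per condition
  and construct. The fusion library therefore exceeds the nominal depth
  by the planted in-peak mass (~5–10%) — depth totals are exact for the
  Dam control and enrichment-inflated for the fusion, which keeps the raw
  in-peak fusion/Dam ratio at `2^peak_effect` exactly.
- **Chromatin annotation.** Each gene carries a five-colour state label
  (peak-target genes are "blue" with probability 0.8, others uniform);
  states tile each chromosome via midpoints between consecutive TSSs, so
  every TSS is covered by its own label. 70% of planted peaks carry a
  PRE (confidence 0.85–1.0, class mix 40/40/10/10
  intergenic/enhancer/promoter/other) at their centre, plus 150
  background PREs with uniform confidence.
- **Regulons.** Five TFs (four activators, one repressor), width-10 PWMs
  with per-column consensus probability 0.90–0.96. Each of the 40 members
  per TF (half drawn from a 30-gene shared core, which makes the regulons
  overlap) gets one exact consensus site in its promoter; 40 decoy
  non-member genes get a one-mismatch site at a designated strong column.
  The planted threshold is the midpoint of the member/decoy z levels,
  computed by scanning the finished genome — so the threshold curve has a
  genuine optimum between decoy dilution (below) and member loss
  (above).
- **Expression.** Regulon members get true l2fc ~ N(−1, 0.25); 65% of
  genes are exact nulls; the remainder are symmetric bystanders
  N(0, 0.5). Observed l2fc = truth + N(0, SE_g) with
  `SE_g = se_scale·(0.1 + 0.2·min(Exp(1), 2))` — a right-skewed but
  bounded family. The truncation matters at this scale: with only 400
  genes, an unbounded exponential tail gives the skewness estimator a
  sampling error larger than the planted signal, which no real
  ~10,000-gene dataset exhibits. A mutant contrast zeroes the
  regulon-driven effects, emulating loss of the repressive complex.

What passing tests show — and don't: recovery at defaults (peak Jaccard
≈ 1, regulon Jaccard ≥ 0.95, τ error ≪ 1 grid step) demonstrates the
pipeline's internal correctness and calibration, on data satisfying its
assumptions exactly (Poisson counts, independent fragments, isolated
promoters, a single planted site class). It does not quantify performance
under mappability artefacts, copy-number variation, overlapping genes, or
motif self-similarity, none of which the generator emulates.

## Numerical choices and scale

Thresholds use strict exceedance (a constant track has no peaks).
Quantiles are numpy linear interpolation. The τ grid is 0.5–15 in steps
of 0.5. Stage seeds derive from the global seed as the first four bytes
of SHA-256("seed:stage") mod 2^31, making every stage independently
reproducible. Default problem sizes (2 × 500 kb chromosomes, 400 genes,
4,000 fragments, 10^6 reads/sample, 100 peak shuffles, 1000 enrichment
shuffles) were chosen so a complete run takes seconds on a laptop while
every planted effect is detectable with wide margins; all are config
fields.

## Known limitations

DE tables are consumed, not fitted (a normal Wald p from l2fc/SE is
generated for synthetic tables only); read alignment, BAM input, bigWig
output, differential-binding intensity models, and the PRE predictor
itself are out of scope. The shuffle null ignores gaps/blacklists and
chromosome-composition effects beyond per-chromosome placement. The
equivalence test assumes normally distributed l2fc estimates with known
SE.
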
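"""Monte Carlo interval-overlap enrichment and chromatin-state proportions.

Peak/PRE enrichment follows the genome-shuffle recipe: the observed number
of query intervals touching the reference is compared with the same count
after placing each query interval uniformly at random on its own
chromosome, length preserved.  The empirical p uses the add-one rule so it
is never exactly zero.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, state_at


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    fold: float
    p_empirical: float
    p_depletion: float
    n_shuffles: int
    seed: int


def shuffle_intervals(
    intervals: pd.DataFrame, genome: GenomeModel, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Place each interval uniformly at random on its own chromosome."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = genome.chrom_lengths
    chroms = intervals["chrom"].to_numpy()
    sizes = (intervals["end"] - intervals["start"]).to_numpy()
    starts = np.empty(len(intervals), dtype=np.int64)
    for i, (c, size) in enumerate(zip(chroms, sizes)):
        L = lengths[c]
        if size > L:
            raise ValueError(f"interval of length {size} exceeds chromosome {c} ({L} bp)")
        starts[i] = rng.integers(0, L - size + 1)
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + sizes})


def overlap_count(query: pd.DataFrame, reference: pd.DataFrame) -> int:
    """Number of query intervals overlapping >= 1 bp of any reference interval."""
    total = 0
    ref_by_chrom = {c: sub.sort_values("start") for c, sub in reference.groupby("chrom")}
    for chrom, sub in query.groupby("chrom", sort=False):
        ref = ref_by_chrom.get(chrom)
        if ref is None:
            continue
        rs = ref["start"].to_numpy()
        re_ = ref["end"].to_numpy()
        # running max of ends guards against contained intervals
        re_max = np.maximum.accumulate(re_)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            i = int(np.searchsorted(rs, e, side="left"))  # refs starting before query end
            if i > 0 and re_max[i - 1] > s:
                total += 1
    return int(total)


def permutation_enrichment(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    genome: GenomeModel,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Shuffle-based overlap enrichment of query intervals in the reference.

    The query (the peak set) is shuffled, not the reference; fold is
    observed over null mean, and one-sided empirical p-values are reported
    for both enrichment and depletion.
    """
    if len(query) == 0 or len(reference) == 0:
        raise ValueError("query and reference must be nonempty")
    if n_shuffles <= 0:
        raise ValueError("n_shuffles must be positive")
    observed = overlap_count(query, reference)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles, dtype=np.int64)
    for k in range(n_shuffles):
        null[k] = overlap_count(shuffle_intervals(query, genome, rng), reference)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    fold = observed / null_mean if null_mean > 0 else np.inf
    p_enrich = (1 + int((null >= observed).sum())) / (1 + n_shuffles)
    p_deplete = (1 + int((null <= observed).sum())) / (1 + n_shuffles)
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        fold=float(fold),
        p_empirical=float(p_enrich),
        p_depletion=float(p_deplete),
        n_shuffles=n_shuffles,
        seed=seed if isinstance(seed, int) else -1,
    )


def select_pres(
    pres: pd.DataFrame, pre_class: str | None = None, min_confidence: float = 0.8
) -> pd.DataFrame:
    """PREs of one class at or above a prediction-confidence threshold."""
    sub = pres[pres["confidence"] >= min_confidence]
    if pre_class is not None:
        sub = sub[sub["pre_class"] == pre_class]
    return sub[["chrom", "start", "end"]].reset_index(drop=True)


def chromatin_state_proportions(
    bound_genes: set[str], genome: GenomeModel
) -> pd.DataFrame:
    """Observed/expected gene allocation to the five chromatin states.

    Each gene is assigned the state covering its transcription start site;
    the ratio per state is the fraction of bound genes in that state over
    the genome-wide fraction.  Genes without a covering state are excluded
    and counted in the ``n_excluded`` attribute of the result.
    """
    states = genome.chromatin_states
    labels = {}
    n_excluded = 0
    for g in genome.genes:
        s = state_at(states, g.chrom, g.tss)
        if s is None:
            n_excluded += 1
            continue
        labels[g.gene_id] = s
    all_counts = pd.Series(labels).value_counts()
    bound_labels = [labels[g] for g in bound_genes if g in labels]
    bound_counts = pd.Series(bound_labels).value_counts()
    from .genome import CHROMATIN_STATES

    rows = []
    n_all = len(labels)
    n_bound = len(bound_labels)
    for state in CHROMATIN_STATES:
        exp_frac = all_counts.get(state, 0) / n_all if n_all else np.nan
        obs_frac = bound_counts.get(state, 0) / n_bound if n_bound else np.nan
        ratio = obs_frac / exp_frac if exp_frac and exp_frac > 0 else np.nan
        rows.append((state, obs_frac, exp_frac, ratio))
    out = pd.DataFrame(rows, columns=["state", "observed_frac", "expected_frac", "ratio"])
    out.attrs["n_excluded"] = n_excluded
    return out
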
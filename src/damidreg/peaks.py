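"""Shuffle-FDR peak calling on GATC-fragment occupancy tracks.

A peak is a run of at least ``min_run`` consecutive fragments whose values
exceed a quantile threshold taken from the track itself.  The null is built
by permuting fragment values within each chromosome: for every observed run
length n the false-discovery estimate is

    FDR(n) = expected_shuffled(# runs of length >= n) / observed(# runs >= n)

and runs with FDR below ``fdr_max`` are reported as peaks on fragment
coordinates.  Replicate peak sets are combined by base-pair intersection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .occupancy import OccupancyTrack

PEAK_COLUMNS = ["chrom", "start", "end", "n_fragments", "mean_signal", "threshold_used", "fdr"]


@dataclass
class PeakSet:
    """Sorted, annotated enriched intervals plus call provenance."""

    peaks: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.peaks.empty and not set(PEAK_COLUMNS[:3]) <= set(self.peaks.columns):
            self.peaks = pd.DataFrame(columns=PEAK_COLUMNS)
        self.peaks = self.peaks.sort_values(["chrom", "start"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def intervals(self) -> pd.DataFrame:
        return self.peaks[["chrom", "start", "end"]].copy()

    def write_bed(self, path) -> None:
        df = self.peaks.copy()
        df["name"] = [f"peak_{i}" for i in range(len(df))]
        with np.errstate(divide="ignore"):
            score = np.minimum(1000, -10 * np.log10(np.maximum(df["fdr"], 1e-300)))
        df["score"] = score.round(1) if len(df) else score
        df["strand"] = "."
        cols = ["chrom", "start", "end", "name", "score", "strand", "n_fragments", "mean_signal", "fdr"]
        df[cols].to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start_index, length)."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _run_length_counts(mask: np.ndarray, min_run: int, max_len: int) -> np.ndarray:
    """counts[n] = number of runs with length >= n, for n in 0..max_len."""
    counts = np.zeros(max_len + 1, dtype=np.int64)
    for _, length in _runs_above(mask):
        if length >= min_run:
            counts[: min(length, max_len) + 1] += 1
    return counts


def call_peaks_fdr(
    track: OccupancyTrack,
    fdr_max: float = 0.01,
    n_shuffles: int = 100,
    min_run: int = 2,
    threshold_q: float = 0.95,
    seed: int = 0,
) -> PeakSet:
    """Call fusion-enriched peaks with a within-chromosome shuffle FDR."""
    fragmap = track.fragmap
    values = track.values
    if len(values) < 10 * min_run:
        raise ValueError("too few fragments for peak calling")
    threshold = float(np.quantile(values, threshold_q))
    mask = values > threshold  # strict: a constant track yields no exceedances

    per_chrom_masks = {c: mask[fragmap.chrom_slice(c)] for c in fragmap.chrom_names}
    observed_runs: list[tuple[str, int, int]] = []
    for chrom, m in per_chrom_masks.items():
        for start_idx, length in _runs_above(m):
            if length >= min_run:
                observed_runs.append((chrom, start_idx, length))

    if not observed_runs:
        return PeakSet(
            pd.DataFrame(columns=PEAK_COLUMNS),
            provenance={
                "sample": track.sample_id,
                "condition": track.condition,
                "threshold": threshold,
                "fdr_max": fdr_max,
                "n_shuffles": n_shuffles,
                "min_run": min_run,
                "threshold_q": threshold_q,
                "seed": seed,
            },
        )

    max_len = max(length for _, _, length in observed_runs)
    obs_ge = np.zeros(max_len + 1, dtype=np.int64)
    for _, _, length in observed_runs:
        obs_ge[: length + 1] += 1

    rng = np.random.default_rng(seed)
    exp_total = np.zeros(max_len + 1, dtype=np.float64)
    for _ in range(n_shuffles):
        for chrom in fragmap.chrom_names:
            v = values[fragmap.chrom_slice(chrom)]
            shuffled = rng.permutation(v)
            exp_total += _run_length_counts(shuffled > threshold, min_run, max_len)
    exp_ge = exp_total / n_shuffles

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_by_len = exp_ge / obs_ge
    fdr_by_len = np.where(obs_ge > 0, fdr_by_len, np.inf)
    # longer runs can only be rarer under the null: enforce monotone non-increase
    for n in range(min_run + 1, max_len + 1):
        fdr_by_len[n] = min(fdr_by_len[n], fdr_by_len[n - 1])

    rows = []
    for chrom, start_idx, length in observed_runs:
        fdr = float(fdr_by_len[length])
        if fdr < fdr_max:
            b = fragmap.boundaries[chrom]
            off = fragmap.offsets[chrom]
            seg = values[off + start_idx : off + start_idx + length]
            rows.append(
                (
                    chrom,
                    int(b[start_idx]),
                    int(b[start_idx + length]),
                    length,
                    float(seg.mean()),
                    threshold,
                    fdr,
                )
            )
    peaks = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(
        peaks,
        provenance={
            "sample": track.sample_id,
            "condition": track.condition,
            "threshold": threshold,
            "fdr_max": fdr_max,
            "n_shuffles": n_shuffles,
            "min_run": min_run,
            "threshold_q": threshold_q,
            "seed": seed,
        },
    )


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended intervals (mergeBed semantics)."""
    if len(intervals) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if (intervals["start"] >= intervals["end"]).any():
        bad = intervals[intervals["start"] >= intervals["end"]]
        raise ValueError(f"malformed intervals (start >= end):\n{bad.head()}")
    out = []
    df = intervals.sort_values(["chrom", "start", "end"], kind="stable")
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or bookended
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        out.append((chrom, int(cur_s), int(cur_e)))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _intersect_two(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        xa = a[a["chrom"] == chrom].sort_values("start")
        xb = b[b["chrom"] == chrom].sort_values("start")
        ia = ib = 0
        sa, ea = xa["start"].to_numpy(), xa["end"].to_numpy()
        sb, eb = xb["start"].to_numpy(), xb["end"].to_numpy()
        while ia < len(sa) and ib < len(sb):
            lo = max(sa[ia], sb[ib])
            hi = min(ea[ia], eb[ib])
            if lo < hi:
                rows.append((chrom, int(lo), int(hi)))
            if ea[ia] <= eb[ib]:
                ia += 1
            else:
                ib += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def intersect_replicate_peaks(peaksets: Sequence[PeakSet]) -> PeakSet:
    """Base-pair-wise intersection of peak regions across all replicates."""
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets to intersect")
    acc = merge_intervals(peaksets[0].intervals())
    for ps in peaksets[1:]:
        acc = _intersect_two(acc, merge_intervals(ps.intervals()))
        if acc.empty:
            break
    prov = {"intersection_of": [ps.provenance for ps in peaksets]}
    out = acc.copy()
    for col, default in (("n_fragments", 0), ("mean_signal", np.nan), ("threshold_used", np.nan), ("fdr", np.nan)):
        out[col] = default
    return PeakSet(out, provenance=prov)


def gene_search_windows(genome: GenomeModel, upstream: int = 2000) -> pd.DataFrame:
    """Gene span extended ``upstream`` bp 5' of the ORF start, strand-aware."""
    rows = []
    lengths = genome.chrom_lengths
    for g in genome.genes:
        if g.strand == "+":
            lo = max(0, min(g.start, g.orf_start - upstream))
            hi = g.end
        else:
            lo = g.start
            hi = min(lengths[g.chrom], max(g.end, g.orf_start + upstream))
        rows.append((g.gene_id, g.chrom, int(lo), int(hi)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def peaks_to_genes(
    peaks: PeakSet, genome: GenomeModel, upstream: int = 2000
) -> pd.DataFrame:
    """Flag genes overlapped by any peak within span + upstream window."""
    windows = gene_search_windows(genome, upstream)
    pk = peaks.intervals()
    records = []
    for _, w in windows.iterrows():
        sub = pk[pk["chrom"] == w["chrom"]]
        hit = sub[(sub["start"] < w["end"]) & (sub["end"] > w["start"])]
        records.append(
            (w["gene_id"], ",".join(f"{r.start}-{r.end}" for r in hit.itertuples()), len(hit) > 0)
        )
    return pd.DataFrame(records, columns=["gene_id", "peaks", "bound"])


@dataclass
class GeneOccupancyDelta:
    gene_id: str
    mean_ratio_cd: float
    mean_ratio_sd: float
    delta: float
    group: str  # "1" higher-on-SD, "2" lower-on-SD, "unchanged"


def compare_occupancy(
    track_cd: OccupancyTrack,
    track_sd: OccupancyTrack,
    genome: GenomeModel,
    min_abs_delta: float = 0.5,
    upstream: int = 2000,
) -> pd.DataFrame:
    """Per-gene occupancy difference between conditions.

    Mean log-ratio over fragments overlapping each gene's search window per
    condition; genes move to group 1 (more fusion binding on SD) or group 2
    (less) when |delta| exceeds ``min_abs_delta``.  Genes overlapping no
    fragment get missing values and no group.
    """
    fragmap = track_cd.fragmap
    windows = gene_search_windows(genome, upstream)
    rows = []
    for _, w in windows.iterrows():
        frags = fragmap.overlapping_fragments(w["chrom"], int(w["start"]), int(w["end"]))
        if frags.size == 0:
            rows.append((w["gene_id"], np.nan, np.nan, np.nan, "na"))
            continue
        m_cd = float(track_cd.values[frags].mean())
        m_sd = float(track_sd.values[frags].mean())
        delta = m_sd - m_cd
        if delta >= min_abs_delta:
            group = "1"
        elif delta <= -min_abs_delta:
            group = "2"
        else:
            group = "unchanged"
        rows.append((w["gene_id"], m_cd, m_sd, delta, group))
    return pd.DataFrame(
        rows, columns=["gene_id", "mean_ratio_cd", "mean_ratio_sd", "delta", "group"]
    )
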
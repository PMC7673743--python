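"""Occupancy ratios, 1x-normalised accessibility, and metaprofiles.

The central quantity is the per-fragment log2(fusion/Dam) occupancy ratio,
computed on depth-normalised counts (counts-per-million) with a pseudocount
so the track is finite everywhere.  The Dam-only control doubles as a
chromatin-accessibility read-out once coverage is normalised to 1x genome.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import FragmentCountTrack, GATCFragmentMap


@dataclass
class OccupancyTrack:
    """Per-fragment log2 fusion/Dam ratio for one condition (one replicate)."""

    condition: str
    values: np.ndarray
    fragmap: GATCFragmentMap
    pseudocount: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.fragmap.n_fragments:
            raise ValueError("track length must equal number of fragments")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("occupancy values must be finite")

    def to_bedgraph(self, path) -> None:
        df = self.fragmap.to_frame()
        df["value"] = self.values
        df[["chrom", "start", "end", "value"]].to_csv(
            path, sep="\t", header=False, index=False, float_format="%.6g"
        )


@dataclass
class CoverageProfile:
    """Mean signal in fixed bins around a set of interval centers."""

    half_width: int
    bin_size: int
    offsets: np.ndarray  # bin-center offsets relative to interval centers
    mean_signal: np.ndarray
    n_intervals: int


def _cpm(track: FragmentCountTrack) -> np.ndarray:
    lib = track.library_size
    if lib <= 0:
        raise ValueError(f"{track.sample_id}: library size must be positive")
    return track.counts * 1e6 / lib


def compute_log_ratio(
    fusion: FragmentCountTrack,
    dam: FragmentCountTrack,
    pseudocount: float = 1.0,
) -> OccupancyTrack:
    """log2((cpm_fusion + psi) / (cpm_dam + psi)) per GATC fragment.

    Depth differences between the two libraries cancel through the CPM
    scaling; the pseudocount keeps empty fragments finite.  Replicates are
    ratioed separately, never pooled here.
    """
    if fusion.fragmap is not dam.fragmap and not all(
        np.array_equal(fusion.fragmap.boundaries[c], dam.fragmap.boundaries[c])
        for c in fusion.fragmap.chrom_names
    ):
        raise ValueError("fusion and Dam tracks use different fragment maps")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = np.log2((_cpm(fusion) + pseudocount) / (_cpm(dam) + pseudocount))
    return OccupancyTrack(
        condition=fusion.condition,
        values=values,
        fragmap=fusion.fragmap,
        pseudocount=pseudocount,
        sample_id=fusion.sample_id,
    )


def normalize_coverage_1x(dam: FragmentCountTrack) -> np.ndarray:
    """Scale per-fragment coverage so mean per-bp coverage over the genome is 1.

    This is the accessibility normalisation used for Dam-only (CATaDa)
    profiles: sum(value_i * length_i) / genome_length == 1 afterwards.
    """
    lib = dam.library_size
    if lib <= 0:
        raise ValueError("zero library: cannot normalise")
    lengths = dam.fragmap.fragment_lengths().astype(float)
    genome_length = float(lengths.sum())
    per_bp = dam.counts / lengths  # read density within each fragment
    scale = genome_length / float(per_bp @ lengths)
    return per_bp * scale


def metaprofile(
    values: np.ndarray,
    fragmap: GATCFragmentMap,
    centers: pd.DataFrame,
    half_width: int = 2500,
    bin_size: int = 50,
) -> CoverageProfile:
    """Average a fragment-resolution track in bins around interval centers.

    For every center the track is sampled at bin midpoints across
    ``[mid - half_width, mid + half_width)``; bins falling off-chromosome
    are ignored in the mean.
    """
    if len(centers) == 0:
        raise ValueError("empty centers")
    n_bins = (2 * half_width) // bin_size
    offsets = -half_width + bin_size * np.arange(n_bins) + bin_size // 2
    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)
    for chrom, sub in centers.groupby("chrom", sort=False):
        if chrom not in fragmap.chrom_names:
            continue
        b = fragmap.boundaries[chrom]
        L = fragmap.chrom_lengths[chrom]
        off = fragmap.offsets[chrom]
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy(dtype=np.int64)
        for mid in mids:
            pos = mid + offsets
            ok = (pos >= 0) & (pos < L)
            if not ok.any():
                continue
            frag = np.searchsorted(b, pos[ok], side="right") - 1
            total[ok] += values[off + frag]
            count[ok] += 1
    mean = np.full(n_bins, np.nan)
    nz = count > 0
    mean[nz] = total[nz] / count[nz]
    return CoverageProfile(half_width, bin_size, offsets, mean, int(len(centers)))
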
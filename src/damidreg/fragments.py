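"""GATC fragment maps and fragment-resolution read counting.

DamID signal lives at the resolution of GATC fragments: the intervals
between consecutive GATC motif occurrences (the motif is its own reverse
complement, so a single forward scan suffices).  Fragment boundaries sit at
GATC motif *start* coordinates; fragments tile each chromosome exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

GATC = "GATC"


def find_gatc_starts(sequence: str) -> np.ndarray:
    """Start positions of every GATC occurrence in a sequence."""
    positions = []
    i = sequence.find(GATC)
    while i != -1:
        positions.append(i)
        i = sequence.find(GATC, i + 1)
    return np.asarray(positions, dtype=np.int64)


@dataclass
class GATCFragmentMap:
    """Ordered GATC fragments per chromosome with flat global indexing.

    ``boundaries[chrom]`` holds ``[0, b_1, ..., b_k, L]`` where the ``b_i``
    are GATC motif starts; fragment ``j`` on that chromosome is
    ``[boundaries[j], boundaries[j+1])``.  Flat fragment ids run over
    chromosomes in their stated order.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    boundaries: dict[str, np.ndarray]
    offsets: dict[str, int] = field(init=False)
    n_fragments: int = field(init=False)

    def __post_init__(self) -> None:
        self.offsets = {}
        off = 0
        for chrom in self.chrom_names:
            b = np.asarray(self.boundaries[chrom], dtype=np.int64)
            if b[0] != 0 or b[-1] != self.chrom_lengths[chrom]:
                raise ValueError(f"{chrom}: boundaries must span [0, L]")
            if np.any(np.diff(b) <= 0):
                raise ValueError(f"{chrom}: boundaries must be strictly increasing")
            self.boundaries[chrom] = b
            self.offsets[chrom] = off
            off += len(b) - 1
        self.n_fragments = off

    def n_fragments_chrom(self, chrom: str) -> int:
        return len(self.boundaries[chrom]) - 1

    def chrom_slice(self, chrom: str) -> slice:
        off = self.offsets[chrom]
        return slice(off, off + self.n_fragments_chrom(chrom))

    def fragment_lengths(self) -> np.ndarray:
        return np.concatenate(
            [np.diff(self.boundaries[c]) for c in self.chrom_names]
        ).astype(np.int64)

    def fragment_index(self, chrom: str, pos: int) -> int:
        """Flat id of the fragment containing ``pos``."""
        b = self.boundaries[chrom]
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.offsets[chrom] + int(np.searchsorted(b, pos, side="right")) - 1

    def overlapping_fragments(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Flat ids of fragments overlapping [start, end) by >= 1 bp."""
        if end <= start:
            return np.empty(0, dtype=np.int64)
        b = self.boundaries[chrom]
        L = self.chrom_lengths[chrom]
        start = max(0, start)
        end = min(L, end)
        if end <= start:
            return np.empty(0, dtype=np.int64)
        first = int(np.searchsorted(b, start, side="right")) - 1
        last = int(np.searchsorted(b, end, side="left"))  # exclusive
        return self.offsets[chrom] + np.arange(first, last, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_names:
            b = self.boundaries[chrom]
            for s, e in zip(b[:-1], b[1:]):
                rows.append((chrom, int(s), int(e)))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        df.insert(0, "fragment_id", np.arange(len(df), dtype=np.int64))
        return df


def build_gatc_fragment_map(genome: GenomeModel) -> GATCFragmentMap:
    """Fragment map with boundaries at every GATC motif start.

    Chromosomes without any GATC yield a single fragment [0, L).
    """
    boundaries = {}
    for name, length, seq in genome.chromosomes:
        if length == 0 or not seq:
            raise ValueError(f"{name}: empty sequence")
        starts = find_gatc_starts(seq)
        starts = starts[(starts > 0) & (starts < length)]
        boundaries[name] = np.concatenate(([0], starts, [length]))
    return GATCFragmentMap(genome.chrom_names, genome.chrom_lengths, boundaries)


@dataclass
class FragmentCountTrack:
    """Per-fragment read counts for one sample/construct."""

    sample_id: str
    condition: str
    construct: str  # "Dam" or "fusion"
    counts: np.ndarray
    fragmap: GATCFragmentMap

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != self.fragmap.n_fragments:
            raise ValueError("counts length must equal number of fragments")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def library_size(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = self.fragmap.to_frame()
        df["count"] = self.counts
        return df


def assign_reads_to_fragments(
    reads: pd.DataFrame,
    fragmap: GATCFragmentMap,
    max_ext: int = 300,
    sample_id: str = "sample",
    condition: str = "NA",
    construct: str = "Dam",
) -> FragmentCountTrack:
    """Extend read starts and count fragment overlaps.

    Each read is extended 3'-ward from its start to ``min(start + max_ext,
    next GATC boundary past the start)`` in read orientation (unstranded
    input is treated as '+'); every fragment the extended read overlaps
    gains one count.  Mirrors the extend-then-bin step of DamID pipelines.
    """
    reads = reads.copy()
    if "strand" not in reads.columns:
        reads["strand"] = "+"
    unknown = sorted(set(reads["chrom"]) - set(fragmap.chrom_names))
    if unknown:
        rows = reads[reads["chrom"].isin(unknown)]
        raise ValueError(f"reads on unknown chromosomes {unknown}: rows {list(rows.index[:10])}")

    counts = np.zeros(fragmap.n_fragments, dtype=np.int64)
    for chrom, sub in reads.groupby("chrom", sort=False):
        b = fragmap.boundaries[chrom]
        L = fragmap.chrom_lengths[chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        if np.any((starts < 0) | (starts >= L)):
            raise ValueError(f"read starts outside {chrom}")
        fwd = (sub["strand"].to_numpy() != "-")
        off = fragmap.offsets[chrom]
        for s, is_fwd in zip(starts, fwd):
            if is_fwd:
                # next boundary strictly past the start
                j = int(np.searchsorted(b, s, side="right"))
                stop = min(s + max_ext, b[j]) if j < len(b) else min(s + max_ext, L)
                lo, hi = s, max(stop, s + 1)
            else:
                # closest boundary at or below the start (b[0] = 0 guarantees j >= 0)
                j = int(np.searchsorted(b, s, side="right")) - 1
                stop = max(s + 1 - max_ext, b[j])
                lo, hi = min(stop, s), s + 1
            first = int(np.searchsorted(b, lo, side="right")) - 1
            last = int(np.searchsorted(b, min(hi, L), side="left"))
            counts[off + first : off + last] += 1
    return FragmentCountTrack(sample_id, condition, construct, counts, fragmap)
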
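"""PWM promoter scanning and motif-z-score regulon inference.

A transcription factor's regulon is the set of genes with at least one
motif hit whose robust z score clears a TF-specific threshold inside the
2-kb window upstream of the ORF start.  Raw log-odds scores are computed at
every genomic position on both strands; robust z uses the genome-wide
median and MAD (scaled by 1.4826 for normal consistency).  Thresholds are
read off a curve of signal-to-noise in member expression change versus
candidate threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .exprstats import bh_fdr
from .genome import GenomeModel

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


@dataclass
class MotifModel:
    """Position weight matrix in log-odds form (width x ACGT)."""

    tf_name: str
    pwm: np.ndarray  # log2(p_base / background)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be width x 4")
        if not np.all(np.isfinite(self.pwm)):
            raise ValueError("pwm weights must be finite")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.pwm.shape[0]

    @classmethod
    def from_probabilities(
        cls, tf_name: str, probs: np.ndarray, background: np.ndarray | None = None
    ) -> "MotifModel":
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        probs = np.asarray(probs, dtype=float)
        return cls(tf_name, np.log2(probs / bg), bg)

    def max_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.pwm, columns=list(BASES)).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, tf_name: str, path: str | Path) -> "MotifModel":
        return cls(tf_name, pd.read_csv(path, sep="\t").to_numpy())


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other letter (N) -> 4, scored as background."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    bad = ~np.isin(arr, [ord(c) for c in "ACGTN"])
    if bad.any():
        raise ValueError("sequence alphabet outside ACGTN")
    return out


def _score_positions(codes: np.ndarray, weights5: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position for a width-w weight matrix."""
    w = weights5.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(w):
        scores += weights5[j, codes[j : j + n]]
    return scores


def robust_z(scores) -> np.ndarray:
    """(x - median) / (1.4826 * MAD)."""
    x = np.asarray(scores, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 scores")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("MAD is zero; robust z undefined (consider another dispersion)")
    return (x - med) / (1.4826 * mad)


def scan_motif(
    genome: GenomeModel, motif: MotifModel, keep_top_frac: float = 0.01
) -> pd.DataFrame:
    """Score the motif at every position on both strands; keep top hits.

    Robust-z location and scale come from *all* scanned positions; only
    hits above the retention floor (top ``keep_top_frac`` of positions, or
    all positions at 1.0) are materialised, bounding memory.  Returns a
    frame (chrom, pos, strand, score, z).
    """
    if not 0 < keep_top_frac <= 1:
        raise ValueError("keep_top_frac must lie in (0, 1]")
    weights5 = np.hstack([motif.pwm, np.zeros((motif.width, 1))])  # N scores as bg
    rc = weights5[::-1, [3, 2, 1, 0, 4]]  # reverse-complement matrix
    per_chrom: list[tuple[str, np.ndarray, np.ndarray]] = []
    all_scores = []
    for name, _, seq in genome.chromosomes:
        if motif.width > len(seq):
            raise ValueError(f"motif wider than chromosome {name}")
        codes = encode_sequence(seq)
        fwd = _score_positions(codes, weights5)
        rev = _score_positions(codes, rc)
        per_chrom.append((name, fwd, rev))
        all_scores.append(fwd)
        all_scores.append(rev)
    pooled = np.concatenate(all_scores)
    med = np.median(pooled)
    mad = np.median(np.abs(pooled - med))
    # a degenerate (near-constant) scan carries no ranking information; keep
    # z at 0 rather than failing, so callers can still inspect raw scores
    scale = 1.4826 * mad if mad > 0 else np.inf
    floor = -np.inf if keep_top_frac >= 1 else np.quantile(pooled, 1 - keep_top_frac)

    rows = []
    for name, fwd, rev in per_chrom:
        for strand, scores in (("+", fwd), ("-", rev)):
            idx = np.flatnonzero(scores >= floor)
            for i in idx:
                rows.append((name, int(i), strand, float(scores[i])))
    hits = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "score"])
    hits["z"] = (hits["score"] - med) / scale
    hits.attrs["median"] = float(med)
    hits.attrs["mad_scale"] = float(scale)
    hits.attrs["tf_name"] = motif.tf_name
    return hits


def promoter_windows(genome: GenomeModel, width: int = 2000) -> pd.DataFrame:
    """Strand-aware windows upstream of the ORF start, clipped to bounds."""
    rows = []
    lengths = genome.chrom_lengths
    for g in genome.genes:
        if g.strand == "+":
            lo, hi = max(0, g.orf_start - width), g.orf_start
        else:
            lo, hi = g.orf_start, min(lengths[g.chrom], g.orf_start + width)
        rows.append((g.gene_id, g.chrom, int(lo), int(hi), g.strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def max_z_per_gene(hits: pd.DataFrame, windows: pd.DataFrame) -> pd.Series:
    """Highest hit z inside each gene's promoter window (NaN if none).

    A hit at position p (either strand) counts when p falls inside the
    window.
    """
    out = pd.Series(np.nan, index=windows["gene_id"], dtype=float)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        hsub = hits[hits["chrom"] == chrom]
        if hsub.empty:
            continue
        pos = hsub["pos"].to_numpy()
        z = hsub["z"].to_numpy()
        order = np.argsort(pos)
        pos, z = pos[order], z[order]
        for gid, s, e in zip(wsub["gene_id"], wsub["start"], wsub["end"]):
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            if hi > lo:
                out[gid] = float(z[lo:hi].max())
    return out


@dataclass
class ThresholdCurve:
    tf_name: str
    grid: np.ndarray
    n_members: np.ndarray
    mean_l2fc: np.ndarray
    sem_l2fc: np.ndarray
    t_stat: np.ndarray
    tau_star: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tau": self.grid,
                "n": self.n_members,
                "mean_l2fc": self.mean_l2fc,
                "sem_l2fc": self.sem_l2fc,
                "t": self.t_stat,
            }
        )


@dataclass
class Regulon:
    tf_name: str
    threshold_z: float
    genes: set[str]
    curve: ThresholdCurve | None = None


def build_regulon(
    hits: pd.DataFrame, windows: pd.DataFrame, tau: float, tf_name: str | None = None
) -> Regulon:
    """Genes with >= 1 promoter hit at z >= tau (either strand)."""
    if np.isnan(tau):
        raise ValueError("tau must not be NaN")
    gene_z = max_z_per_gene(hits, windows)
    members = set(gene_z.index[gene_z >= tau])
    return Regulon(
        tf_name=tf_name or hits.attrs.get("tf_name", "TF"),
        threshold_z=float(tau),
        genes=members,
    )


def threshold_curve(
    hits: pd.DataFrame,
    windows: pd.DataFrame,
    de: pd.DataFrame,
    tau_grid,
    n_min: int = 20,
) -> ThresholdCurve:
    """Signal-to-noise of member expression change along a threshold grid.

    For each candidate tau the members' mean l2fc, its standard error, and
    t(tau) = |mean| / (sd / sqrt(n)) are recorded.  tau* is the centre of
    the plateau of near-maximal t among grid points with n(tau) >= n_min —
    a choice stable under grid refinement (the automated stand-in for
    picking the point of maximum information content by eye).
    """
    grid = np.asarray(sorted(tau_grid), dtype=float)
    gene_z = max_z_per_gene(hits, windows)
    l2fc = de.set_index("gene_id")["l2fc"]
    common = gene_z.index.intersection(l2fc.index)
    gene_z = gene_z[common]
    l2fc = l2fc[common]

    n_arr = np.zeros(len(grid), dtype=np.int64)
    mean_arr = np.full(len(grid), np.nan)
    sem_arr = np.full(len(grid), np.nan)
    t_arr = np.full(len(grid), np.nan)
    for i, tau in enumerate(grid):
        sel = l2fc[gene_z >= tau]
        n = len(sel)
        n_arr[i] = n
        if n >= 2:
            m = float(sel.mean())
            sd = float(sel.std(ddof=1))
            mean_arr[i] = m
            sem_arr[i] = sd / np.sqrt(n)
            t_arr[i] = np.abs(m) / (sd / np.sqrt(n)) if sd > 0 else np.inf
    eligible = np.flatnonzero((n_arr >= n_min) & np.isfinite(t_arr))
    if eligible.size == 0:
        raise ValueError("no grid point yields a regulon of size >= n_min")
    t_max = t_arr[eligible].max()
    plateau = eligible[t_arr[eligible] >= t_max * (1 - 1e-3)]
    tau_star = float(grid[plateau[len(plateau) // 2]])
    return ThresholdCurve(
        tf_name=hits.attrs.get("tf_name", "TF"),
        grid=grid,
        n_members=n_arr,
        mean_l2fc=mean_arr,
        sem_l2fc=sem_arr,
        t_stat=t_arr,
        tau_star=tau_star,
    )


@dataclass
class OverlapTestResult:
    tf_a: str
    tf_b: str
    in_both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p: float
    q: float = np.nan


def regulon_overlap_tests(
    regulons: list[Regulon], universe: set[str]
) -> list[OverlapTestResult]:
    """Pairwise Fisher exact tests of regulon co-membership over a universe."""
    if not universe:
        raise ValueError("empty gene universe")
    for r in regulons:
        if not r.genes <= universe:
            raise ValueError(f"regulon {r.tf_name} not contained in universe")
    results = []
    for i in range(len(regulons)):
        for j in range(i + 1, len(regulons)):
            a, b = regulons[i].genes, regulons[j].genes
            both = len(a & b)
            a_only = len(a - b)
            b_only = len(b - a)
            neither = len(universe) - both - a_only - b_only
            table = [[both, a_only], [b_only, neither]]
            odds, p = fisher_exact(table, alternative="two-sided")
            results.append(
                OverlapTestResult(
                    regulons[i].tf_name,
                    regulons[j].tf_name,
                    both,
                    a_only,
                    b_only,
                    neither,
                    float(odds),
                    float(p),
                )
            )
    qs = bh_fdr([r.p for r in results]) if results else []
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
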
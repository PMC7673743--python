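"""Synthetic genome, DamID counts and expression tables with planted truth.

The generator emulates the statistical structure the downstream analysis
assumes: a small multi-chromosome genome whose GATC sites occur at a
controlled rate; fusion/Dam fragment counts with occupancy peaks that are
shared, gained or lost between a control (CD) and sugar (SD) condition;
PRE-like intervals and five-colour chromatin states correlated with the
planted binding; and five transcription-factor regulons whose repression
drives a negatively skewed l2fc distribution.

Background sequence is i.i.d. uniform; GATC motifs are planted explicitly
at exponential-gap positions and accidental occurrences are scrubbed, so
the fragment structure is under exact control.  Motif sites (exact
consensus for true regulon members, one strong-column mismatch for decoy
genes) are planted inside 2-kb promoter windows, which makes the upstream
window rule the discriminating feature for regulon recovery and gives the
threshold-selection curve a genuine optimum between the decoy and member
z-score levels.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exprstats import bh_fdr
from .fragments import GATCFragmentMap, FragmentCountTrack, build_gatc_fragment_map
from .genome import (
    CHROMATIN_STATES,
    PRE_CLASSES,
    GeneAnnotation,
    GenomeModel,
    PRERecord,
)
from .motifs import BASES, MotifModel, promoter_windows, scan_motif

CONDITIONS = ("CD", "SD")
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the desk-scale conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 500_000
    gatc_rate: float = 0.004          # ~250 bp fragments, fly-like
    n_genes: int = 400
    n_peaks_shared: int = 18          # ~70% of peaks shared between diets
    n_peaks_gained: int = 7           # SD-only occupancy peaks
    n_peaks_lost: int = 7             # CD-only occupancy peaks
    peak_effect: float = 2.0          # mean log2 fusion/Dam enrichment in peaks
    read_depth: int = 1_000_000       # expected reads per sample
    n_tfs: int = 5                    # four activators + one repressor
    regulon_effect: float = -1.0      # mean true l2fc of repressed targets
    frac_null: float = 0.65           # fraction of genes with true l2fc 0
    se_scale: float = 1.0
    n_replicates: int = 2
    # generator-internal structure
    regulon_size: int = 40
    regulon_core_size: int = 30       # shared pool driving regulon overlap
    motif_width: int = 10
    promoter_width: int = 2000
    peak_frags_min: int = 4
    peak_frags_max: int = 6
    member_l2fc_sd: float = 0.25
    bystander_l2fc_sd: float = 0.5
    accessibility_boost: float = 4.0
    n_accessible_genes: int = 100
    n_background_pres: int = 150
    pre_at_peak_prob: float = 0.7

    def __post_init__(self) -> None:
        counts = (
            self.n_chroms, self.chrom_length_bp, self.n_genes, self.n_peaks_shared,
            self.n_peaks_gained, self.n_peaks_lost, self.read_depth, self.n_tfs,
            self.n_replicates, self.regulon_size,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        for p, name in ((self.gatc_rate, "gatc_rate"), (self.frac_null, "frac_null"),
                        (self.pre_at_peak_prob, "pre_at_peak_prob")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.peak_effect < 0:
            raise ValueError("peak_effect must be nonnegative")
        if self.se_scale < 0:
            raise ValueError("se_scale must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Planted ground truth used by parameter-recovery tests."""

    planted_peaks: dict[str, pd.DataFrame]       # condition -> intervals (+gene)
    peak_fragments: dict[str, np.ndarray]        # condition -> flat fragment ids
    peak_genes: dict[str, list[str]]             # shared/gained/lost -> genes
    true_regulons: dict[str, set[str]]
    true_l2fc: dict[str, float]
    tf_thresholds: dict[str, float]
    motifs: list[MotifModel]
    pcl_target_genes: set[str]
    accessible_genes: set[str]
    fragmap: GATCFragmentMap | None = field(default=None, repr=False)


# --------------------------------------------------------------------------
# sequence assembly helpers

def _random_consensus(rng: np.random.Generator, width: int) -> str:
    while True:
        cons = "".join(BASES[i] for i in rng.integers(0, 4, size=width))
        if "GATC" not in cons and "GATC" not in cons.translate(_COMP)[::-1]:
            return cons


def _pwm_probs(rng: np.random.Generator, consensus: str, decoy_col: int) -> np.ndarray:
    width = len(consensus)
    probs = np.empty((width, 4))
    for j, base in enumerate(consensus):
        p = 0.95 if j == decoy_col else rng.uniform(0.90, 0.96)
        probs[j, :] = (1 - p) / 3
        probs[j, BASES.index(base)] = p
    return probs


def _plant_gatc_positions(
    rng: np.random.Generator, length: int, rate: float, protected: np.ndarray
) -> np.ndarray:
    """Exponential-gap GATC starts, >= 4 bp apart, clear of protected bases."""
    if rate <= 0:
        return np.empty(0, dtype=np.int64)
    positions = []
    pos = int(max(4, round(rng.exponential(1.0 / rate))))
    while pos <= length - 4:
        lo, hi = max(0, pos - 3), min(length, pos + 7)
        if protected[lo:hi].any():
            pos += 4
            continue
        positions.append(pos)
        pos += int(max(4, round(rng.exponential(1.0 / rate))))
    return np.asarray(positions, dtype=np.int64)


def _scrub_accidental_gatc(
    seq: np.ndarray, planted: set[int], protected: np.ndarray
) -> None:
    """Mutate accidental GATC occurrences in place, sparing protected bases."""
    base_codes = {b: i for i, b in enumerate(BASES)}
    target = np.array([base_codes[c] for c in "GATC"], dtype=seq.dtype)
    for _ in range(20):
        hits = np.flatnonzero(
            (seq[:-3] == target[0]) & (seq[1:-2] == target[1])
            & (seq[2:-1] == target[2]) & (seq[3:] == target[3])
        )
        dirty = [h for h in hits if int(h) not in planted]
        if not dirty:
            return
        for h in dirty:
            if seq[h : h + 4].tolist() != target.tolist():
                continue  # already broken by an earlier mutation this pass
            for i in range(h, h + 4):
                if not protected[i]:
                    seq[i] = (seq[i] + 1) % 4
                    break
            else:
                raise RuntimeError("GATC occurrence fully inside protected bases")
    raise RuntimeError("failed to scrub accidental GATC sites")


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


# --------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[GenomeModel, SimTruth]:
    """Build the toy genome with planted peaks, regulons, states and PREs."""
    rng = np.random.default_rng(config.seed)
    n_chroms = config.n_chroms
    L = config.chrom_length_bp
    if n_chroms == 0 or L == 0:
        raise ValueError("need at least one nonempty chromosome")

    # ---- gene layout: fixed-stride slots so promoter windows never collide
    genes_per_chrom = [config.n_genes // n_chroms] * n_chroms
    for i in range(config.n_genes % n_chroms):
        genes_per_chrom[i] += 1
    gene_len_lo, gene_len_hi = 300, 500
    slot_bp = config.promoter_width + gene_len_hi
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    genes: list[GeneAnnotation] = []
    gene_windows: dict[str, tuple[str, int, int]] = {}  # gene -> (chrom, lo, hi)
    for ci, (chrom, n_c) in enumerate(zip(chrom_names, genes_per_chrom)):
        if n_c == 0:
            continue
        stride = L // n_c
        if stride < slot_bp:
            raise ValueError(
                f"chromosome of {L} bp too short for {n_c} genes "
                f"(needs {slot_bp} bp per gene)"
            )
        for k in range(n_c):
            gid = f"g{len(genes):04d}"
            glen = int(rng.integers(gene_len_lo, gene_len_hi + 1))
            need = config.promoter_width + glen
            off = int(rng.integers(0, stride - need + 1))
            s = k * stride + off
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                w_lo, w_hi = s, s + config.promoter_width
                g_start, g_end = w_hi, w_hi + glen
                orf_start = g_start
            else:
                g_start, g_end = s, s + glen
                orf_start = g_end
                w_lo, w_hi = orf_start, orf_start + config.promoter_width
            genes.append(GeneAnnotation(gid, chrom, strand, g_start, g_end, orf_start))
            gene_windows[gid] = (chrom, w_lo, w_hi)
    gene_ids = [g.gene_id for g in genes]
    gene_by_id = {g.gene_id: g for g in genes}

    # ---- transcription factors, true regulons, planted motif sites
    n_tfs = config.n_tfs
    tf_names = [f"act{i + 1}" for i in range(max(0, n_tfs - 1))] + (
        ["rep1"] if n_tfs >= 1 else []
    )
    motifs: list[MotifModel] = []
    consensi: dict[str, str] = {}
    decoy_col = config.motif_width // 2
    for tf in tf_names:
        cons = _random_consensus(rng, config.motif_width)
        consensi[tf] = cons
        motifs.append(MotifModel.from_probabilities(tf, _pwm_probs(rng, cons, decoy_col)))

    true_regulons: dict[str, set[str]] = {}
    decoy_genes: dict[str, list[str]] = {}
    if n_tfs > 0 and config.regulon_size > 0:
        if config.regulon_size > config.n_genes:
            raise ValueError("regulon_size exceeds n_genes")
        core = [str(g) for g in rng.choice(gene_ids,
                size=min(config.regulon_core_size, len(gene_ids)), replace=False)]
        for tf in tf_names:
            n_core = min(len(core), config.regulon_size // 2)
            picked = set(map(str, rng.choice(core, size=n_core, replace=False)))
            rest_pool = [g for g in gene_ids if g not in picked]
            picked |= set(map(str, rng.choice(rest_pool,
                          size=config.regulon_size - n_core, replace=False)))
            true_regulons[tf] = picked
        member_union = set().union(*true_regulons.values())
        for tf in tf_names:
            pool = [g for g in gene_ids if g not in member_union]
            n_decoy = min(len(pool), config.regulon_size)
            decoy_genes[tf] = [str(g) for g in rng.choice(pool, size=n_decoy, replace=False)]
    else:
        member_union = set()
        for tf in tf_names:
            true_regulons[tf] = set()
            decoy_genes[tf] = []

    # site planting bookkeeping: per chromosome protected mask + sequences
    seqs = {c: rng.integers(0, 4, size=L).astype(np.int8) for c in chrom_names}
    protected = {c: np.zeros(L, dtype=bool) for c in chrom_names}

    def plant_site(gene_id: str, site: str) -> None:
        chrom, w_lo, w_hi = gene_windows[gene_id]
        width = len(site)
        for _ in range(200):
            start = int(rng.integers(w_lo + 2, w_hi - width - 1))
            # 3-bp margin: abutting sites could otherwise form GATC at the junction
            if not protected[chrom][max(0, start - 3) : start + width + 3].any():
                break
        else:
            raise RuntimeError(f"could not place motif site in promoter of {gene_id}")
        if rng.random() < 0.5:
            site = site.translate(_COMP)[::-1]
        codes = np.array([BASES.index(b) for b in site], dtype=np.int8)
        seqs[chrom][start : start + width] = codes
        protected[chrom][start : start + width] = True

    def decoy_site(tf: str) -> str:
        cons = consensi[tf]
        alts = [b for b in BASES if b != cons[decoy_col]]
        rng.shuffle(alts)
        for alt in alts:
            s = cons[:decoy_col] + alt + cons[decoy_col + 1 :]
            if "GATC" not in s and "GATC" not in s.translate(_COMP)[::-1]:
                return s
        raise RuntimeError("no GATC-free decoy variant")  # 3 variants: unreachable

    for tf in tf_names:
        for g in sorted(true_regulons[tf]):
            plant_site(g, consensi[tf])
        for g in decoy_genes[tf]:
            plant_site(g, decoy_site(tf))

    # ---- GATC structure and scrubbing
    planted_gatc: dict[str, np.ndarray] = {}
    gatc_codes = np.array([BASES.index(b) for b in "GATC"], dtype=np.int8)
    for chrom in chrom_names:
        pos = _plant_gatc_positions(rng, L, config.gatc_rate, protected[chrom])
        planted_gatc[chrom] = pos
        for p in pos:
            seqs[chrom][p : p + 4] = gatc_codes
            protected[chrom][p : p + 4] = True
        _scrub_accidental_gatc(seqs[chrom], set(pos.tolist()), protected[chrom])

    chromosomes = [(c, L, _codes_to_str(seqs[c])) for c in chrom_names]

    # ---- planted occupancy peaks on GATC-fragment boundaries
    n_peaks_total = config.n_peaks_shared + config.n_peaks_gained + config.n_peaks_lost
    if n_peaks_total > len(gene_ids):
        raise ValueError("more planted peaks requested than genes available")
    interim = GenomeModel(chromosomes=chromosomes, genes=genes)
    fragmap = build_gatc_fragment_map(interim)
    target_genes = [str(g) for g in rng.choice(gene_ids, size=n_peaks_total, replace=False)]
    peak_genes = {
        "shared": target_genes[: config.n_peaks_shared],
        "gained": target_genes[config.n_peaks_shared : config.n_peaks_shared + config.n_peaks_gained],
        "lost": target_genes[config.n_peaks_shared + config.n_peaks_gained :],
    }

    def peak_for_gene(gid: str) -> tuple[str, int, int, np.ndarray]:
        chrom, w_lo, w_hi = gene_windows[gid]
        frags = fragmap.overlapping_fragments(chrom, w_lo, w_hi)
        if frags.size == 0:
            raise RuntimeError(f"promoter of {gid} holds no GATC fragment")
        k = int(rng.integers(config.peak_frags_min, config.peak_frags_max + 1))
        k = min(k, frags.size)
        i0 = int(rng.integers(0, frags.size - k + 1))
        ids = frags[i0 : i0 + k]
        off = fragmap.offsets[chrom]
        b = fragmap.boundaries[chrom]
        return chrom, int(b[ids[0] - off]), int(b[ids[-1] - off + 1]), ids

    peak_records: dict[str, list] = {c: [] for c in CONDITIONS}
    peak_frag_ids: dict[str, list[np.ndarray]] = {c: [] for c in CONDITIONS}
    for category, conds in (("shared", ("CD", "SD")), ("gained", ("SD",)), ("lost", ("CD",))):
        for gid in peak_genes[category]:
            chrom, s, e, ids = peak_for_gene(gid)
            for cond in conds:
                peak_records[cond].append((chrom, s, e, gid, category))
                peak_frag_ids[cond].append(ids)
    planted_peaks = {
        cond: pd.DataFrame(
            peak_records[cond], columns=["chrom", "start", "end", "gene_id", "category"]
        ).sort_values(["chrom", "start"]).reset_index(drop=True)
        for cond in CONDITIONS
    }
    peak_fragments = {
        cond: (np.unique(np.concatenate(peak_frag_ids[cond]))
               if peak_frag_ids[cond] else np.empty(0, dtype=np.int64))
        for cond in CONDITIONS
    }

    # ---- chromatin states: segments around each TSS carry the gene's label
    pcl_targets = set(target_genes)
    state_rows = []
    for chrom in chrom_names:
        cgenes = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.tss)
        if not cgenes:
            state_rows.append((chrom, 0, L, str(rng.choice(CHROMATIN_STATES))))
            continue
        labels = []
        for g in cgenes:
            if g.gene_id in pcl_targets and rng.random() < 0.8:
                labels.append("blue")
            else:
                labels.append(str(rng.choice(CHROMATIN_STATES)))
        tss = [g.tss for g in cgenes]
        bounds = [0] + [(tss[i] + tss[i + 1]) // 2 for i in range(len(tss) - 1)] + [L]
        for i, lab in enumerate(labels):
            state_rows.append((chrom, bounds[i], bounds[i + 1], lab))
    chromatin_states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])

    # ---- PREs: most planted peaks carry one; background PREs everywhere
    pres: list[PRERecord] = []
    seen_peaks = set()
    for cond in CONDITIONS:
        for row in planted_peaks[cond].itertuples():
            key = (row.chrom, row.start, row.end)
            if key in seen_peaks:
                continue
            seen_peaks.add(key)
            if rng.random() < config.pre_at_peak_prob:
                mid = (row.start + row.end) // 2
                half = int(rng.integers(150, 400))
                cls = str(rng.choice(PRE_CLASSES, p=[0.4, 0.4, 0.1, 0.1]))
                conf = float(rng.uniform(0.85, 1.0))
                pres.append(PRERecord(row.chrom, max(0, mid - half),
                                      min(L, mid + half), cls, conf))
    for _ in range(config.n_background_pres):
        chrom = str(rng.choice(chrom_names))
        size = int(rng.integers(300, 800))
        s = int(rng.integers(0, L - size + 1))
        pres.append(PRERecord(chrom, s, s + size, str(rng.choice(PRE_CLASSES)),
                              float(rng.uniform(0.0, 1.0))))

    genome = GenomeModel(
        chromosomes=chromosomes, genes=genes, chromatin_states=chromatin_states, pres=pres
    )

    # ---- TF-specific z thresholds: midpoint of decoy/member z levels
    tf_thresholds: dict[str, float] = {}
    for tf, motif in zip(tf_names, motifs):
        hits = scan_motif(genome, motif, keep_top_frac=0.001)
        med, scale = hits.attrs["median"], hits.attrs["mad_scale"]
        z_member = (motif.max_score() - med) / scale
        cons_code = BASES.index(consensi[tf][decoy_col])
        # any non-consensus base at the decoy column carries the same weight
        penalty = motif.pwm[decoy_col, cons_code] - np.min(motif.pwm[decoy_col])
        z_decoy = (motif.max_score() - penalty - med) / scale
        tf_thresholds[tf] = float((z_member + z_decoy) / 2)

    # ---- true expression effects
    n_null_target = int(round(config.frac_null * config.n_genes))
    nonmembers = [g for g in gene_ids if g not in member_union]
    true_l2fc = {}
    rng.shuffle(nonmembers)
    null_from_nonmembers = nonmembers[:n_null_target]
    bystanders = nonmembers[n_null_target:]
    members = sorted(member_union)
    spill = n_null_target - len(null_from_nonmembers)
    if spill > 0 and members:
        nulled_members = set(map(str, rng.choice(members, size=min(spill, len(members)),
                                                 replace=False)))
    else:
        nulled_members = set()
    for g in null_from_nonmembers:
        true_l2fc[g] = 0.0
    for g in bystanders:
        true_l2fc[g] = float(rng.normal(0.0, config.bystander_l2fc_sd))
    for g in members:
        if g in nulled_members or config.regulon_effect == 0.0:
            true_l2fc[g] = 0.0
        else:
            true_l2fc[g] = float(rng.normal(config.regulon_effect, config.member_l2fc_sd))

    accessible = set(map(str, rng.choice(
        gene_ids, size=min(config.n_accessible_genes, len(gene_ids)), replace=False
    ))) if gene_ids else set()

    truth = SimTruth(
        planted_peaks=planted_peaks,
        peak_fragments=peak_fragments,
        peak_genes=peak_genes,
        true_regulons=true_regulons,
        true_l2fc=true_l2fc,
        tf_thresholds=tf_thresholds,
        motifs=motifs,
        pcl_target_genes=pcl_targets,
        accessible_genes=accessible,
        fragmap=fragmap,
    )
    return genome, truth


def simulate_damid_counts(
    genome: GenomeModel, truth: SimTruth, config: SimConfig
) -> dict[str, FragmentCountTrack]:
    """Poisson fragment counts for Dam and fusion, both conditions, replicates.

    Dam rates follow a lognormal per-fragment accessibility (boosted at the
    planted accessible promoters) scaled to ``read_depth`` expected reads;
    fusion rates multiply the Dam rate by ``2**peak_effect`` inside the
    planted peaks of the matching condition.
    """
    rng = np.random.default_rng([config.seed, 7])
    fragmap = truth.fragmap or build_gatc_fragment_map(genome)
    if fragmap.n_fragments == 0:
        raise ValueError("empty fragment map")
    lengths = fragmap.fragment_lengths().astype(float)
    access = rng.lognormal(mean=0.0, sigma=0.5, size=fragmap.n_fragments)
    windows = promoter_windows(genome, config.promoter_width)
    for row in windows[windows["gene_id"].isin(truth.accessible_genes)].itertuples():
        frags = fragmap.overlapping_fragments(row.chrom, row.start, row.end)
        access[frags] *= config.accessibility_boost
    base_rate = access * lengths
    base_rate *= config.read_depth / base_rate.sum()

    tracks: dict[str, FragmentCountTrack] = {}
    mult = 2.0 ** config.peak_effect
    for cond in CONDITIONS:
        fusion_rate = base_rate.copy()
        fusion_rate[truth.peak_fragments[cond]] *= mult
        for r in range(1, config.n_replicates + 1):
            for construct, rate in (("Dam", base_rate), ("fusion", fusion_rate)):
                sid = f"{construct}_{cond}_r{r}"
                counts = rng.poisson(rate)
                tracks[sid] = FragmentCountTrack(sid, cond, construct, counts, fragmap)
    return tracks


def simulate_expression_tables(
    genome: GenomeModel, truth: SimTruth, config: SimConfig
) -> dict[str, pd.DataFrame]:
    """DE tables per contrast: observed l2fc = true + Normal(0, SE_g).

    SE_g = se_scale * (0.1 + 0.2 * min(Exponential(1), 2)) gives a
    heavy-ish right tail mimicking low-count genes while staying bounded,
    as the gene-wise SEs of detection-filtered genes are in practice;
    p-values are two-sided normal tests of the observed l2fc against zero,
    q-values BH-adjusted.  The mutant contrast zeroes the regulon-driven
    effects, emulating loss of the repressive complex.
    """
    rng = np.random.default_rng([config.seed, 11])
    gene_ids = [g.gene_id for g in genome.genes]
    member_union = set().union(*truth.true_regulons.values()) if truth.true_regulons else set()
    contrasts = {
        "SD_vs_CD": {g: truth.true_l2fc.get(g, 0.0) for g in gene_ids},
        "SD_vs_CD_mutant": {
            g: (0.0 if g in member_union else truth.true_l2fc.get(g, 0.0))
            for g in gene_ids
        },
    }
    out = {}
    for name, effects in contrasts.items():
        base_mean = rng.lognormal(mean=5.0, sigma=1.0, size=len(gene_ids))
        se = config.se_scale * (
            0.1 + 0.2 * np.minimum(rng.exponential(1.0, size=len(gene_ids)), 2.0)
        )
        true = np.array([effects[g] for g in gene_ids])
        obs = true + (rng.normal(0.0, 1.0, size=len(gene_ids)) * se if config.se_scale > 0
                      else 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, np.abs(obs) / np.where(se > 0, se, 1.0), np.inf)
            z = np.where((se == 0) & (obs == 0), 0.0, z)
        p = 2 * norm.sf(z)
        df = pd.DataFrame(
            {"gene_id": gene_ids, "base_mean": base_mean, "l2fc": obs, "se": se, "p": p}
        )
        df["q"] = bh_fdr(df["p"].to_numpy())
        out[name] = df
    return out
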
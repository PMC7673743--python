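"""End-to-end synthetic-to-report pipeline.

One config and one global seed drive: genome simulation, fragment counts,
log-ratio tracks, shuffle-FDR peak calling with replicate intersection,
PRE/chromatin-state enrichment, expression post-statistics, and regulon
inference — then a machine-readable report including truth-recovery
metrics (peak base-pair Jaccard, regulon Jaccard, threshold error).

Stage seeds derive deterministically from the global seed by hashing the
stage name, so stages are reproducible in isolation.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .enrichment import chromatin_state_proportions, permutation_enrichment, select_pres
from .exprstats import equivalence_test, l2fc_skewness
from .fragments import build_gatc_fragment_map
from .genome import GenomeModel
from .motifs import Regulon, build_regulon, promoter_windows, scan_motif, threshold_curve
from .occupancy import compute_log_ratio, metaprofile
from .peaks import (
    PeakSet,
    _intersect_two,
    call_peaks_fdr,
    compare_occupancy,
    intersect_replicate_peaks,
    merge_intervals,
)
from .simulate import (
    CONDITIONS,
    SimConfig,
    SimTruth,
    simulate_damid_counts,
    simulate_expression_tables,
    simulate_genome,
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    fdr_max: float = 0.01
    n_shuffles_peaks: int = 100
    n_shuffles_enrichment: int = 1000
    min_run: int = 2
    threshold_q: float = 0.95
    fold_bound: float = 1.5
    alpha_q: float = 0.1
    min_abs_delta: float = 0.5
    upstream: int = 2000
    metaprofile_half_width: int = 2500
    metaprofile_bin: int = 50
    tau_grid_start: float = 0.5
    tau_grid_stop: float = 15.0
    tau_grid_step: float = 0.5
    tau_overrides: dict[str, float] = field(default_factory=dict)
    keep_top_frac: float = 0.01
    n_min_regulon: int = 20
    pre_min_confidence: float = 0.8

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def tau_grid(self) -> np.ndarray:
        return np.arange(self.tau_grid_start, self.tau_grid_stop + 1e-9, self.tau_grid_step)


class RunReport(BaseModel):
    """Validated report schema; every numeric field must be finite or null."""

    model_config = ConfigDict(extra="forbid")

    version: str
    seed: int
    config_hash: str
    config: dict
    peaks: dict
    recovery: dict
    enrichment: dict
    chromatin_states: dict
    metaprofile: dict
    expression: dict
    occupancy_groups: dict
    regulons: dict


def bp_jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-pair Jaccard index of two interval sets."""
    ma, mb = merge_intervals(a[["chrom", "start", "end"]]), merge_intervals(b[["chrom", "start", "end"]])
    if ma.empty and mb.empty:
        return float("nan")
    inter = _intersect_two(ma, mb)
    bp_i = int((inter["end"] - inter["start"]).sum()) if len(inter) else 0
    bp_a = int((ma["end"] - ma["start"]).sum())
    bp_b = int((mb["end"] - mb["start"]).sum())
    union = bp_a + bp_b - bp_i
    return bp_i / union if union else float("nan")


def _any_overlap_fraction(a: pd.DataFrame, b: pd.DataFrame) -> float:
    from .enrichment import overlap_count

    n = len(a) + len(b)
    if n == 0:
        return float("nan")
    return (overlap_count(a, b) + overlap_count(b, a)) / n


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute simulate -> tracks -> peaks -> enrichment -> expression -> regulons."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # ---- stage: simulate
    sim_cfg = SimConfig(**{**config.sim.to_dict(), "seed": stage_seed(config.seed, "simulate")})
    genome, truth = simulate_genome(sim_cfg)
    fragmap = truth.fragmap or build_gatc_fragment_map(genome)
    tracks = simulate_damid_counts(genome, truth, sim_cfg)
    de_tables = simulate_expression_tables(genome, truth, sim_cfg)
    if out is not None:
        genome.write_fasta(out / "genome.fa")
        genome.write_gff3(out / "genes.gff3")
        genome.write_states_bed(out / "states.bed")
        genome.write_pres_bed(out / "pres.bed")
        (out / "de").mkdir(exist_ok=True)
        for name, df in de_tables.items():
            df.to_csv(out / "de" / f"{name}.tsv", sep="\t", index=False)

    # ---- stage: occupancy ratios (replicates kept separate)
    ratio_tracks: dict[str, list] = {}
    for cond in CONDITIONS:
        ratio_tracks[cond] = []
        for r in range(1, sim_cfg.n_replicates + 1):
            fusion = tracks[f"fusion_{cond}_r{r}"]
            dam = tracks[f"Dam_{cond}_r{r}"]
            ratio_tracks[cond].append(compute_log_ratio(fusion, dam))
    mean_tracks = {}
    for cond in CONDITIONS:
        t0 = ratio_tracks[cond][0]
        mean_values = np.mean([t.values for t in ratio_tracks[cond]], axis=0)
        mean_tracks[cond] = type(t0)(
            condition=cond, values=mean_values, fragmap=t0.fragmap,
            pseudocount=t0.pseudocount, sample_id=f"mean_{cond}",
        )
    if out is not None:
        for cond in CONDITIONS:
            for i, t in enumerate(ratio_tracks[cond], start=1):
                t.to_bedgraph(out / f"ratio_{cond}_r{i}.bedgraph")

    # ---- stage: peak calling per replicate, intersected across replicates
    peak_seed = stage_seed(config.seed, "peaks")
    called: dict[str, PeakSet] = {}
    for cond in CONDITIONS:
        reps = [
            call_peaks_fdr(
                t, fdr_max=config.fdr_max, n_shuffles=config.n_shuffles_peaks,
                min_run=config.min_run, threshold_q=config.threshold_q,
                seed=peak_seed + i,
            )
            for i, t in enumerate(ratio_tracks[cond])
        ]
        called[cond] = intersect_replicate_peaks(reps) if len(reps) > 1 else reps[0]
        if out is not None:
            called[cond].write_bed(out / f"peaks_{cond}.bed")
    shared_fraction = _any_overlap_fraction(called["CD"].intervals(), called["SD"].intervals())

    # ---- stage: enrichment vs PREs and chromatin states
    pres = genome.pres_frame()
    enr_seed = stage_seed(config.seed, "enrichment")
    enrichment_block: dict[str, dict] = {}
    query = called["SD"].intervals()
    if len(query) > 0:
        for label, pre_class in (("all", None), ("intergenic", "intergenic"), ("enhancer", "enhancer")):
            ref = select_pres(pres, pre_class, config.pre_min_confidence)
            if len(ref) == 0:
                continue
            res = permutation_enrichment(
                query, ref, genome, n_shuffles=config.n_shuffles_enrichment, seed=enr_seed
            )
            enrichment_block[label] = {
                "observed": res.observed, "null_mean": res.null_mean,
                "fold": res.fold, "p_empirical": res.p_empirical,
            }
    from .peaks import peaks_to_genes

    bound = peaks_to_genes(called["SD"], genome, upstream=config.upstream)
    bound_genes = set(bound.loc[bound["bound"], "gene_id"])
    state_table = chromatin_state_proportions(bound_genes, genome) if bound_genes else None
    state_block: dict = {"n_bound_genes": len(bound_genes)}
    if state_table is not None:
        finite = state_table.dropna(subset=["ratio"])
        state_block["ratios"] = dict(zip(state_table["state"], state_table["ratio"]))
        state_block["max_state"] = (
            str(finite.loc[finite["ratio"].idxmax(), "state"]) if len(finite) else None
        )

    # ---- stage: metaprofile of SD occupancy at high-confidence PREs
    meta_block: dict = {}
    pre_centers = select_pres(pres, None, config.pre_min_confidence)
    if len(pre_centers) > 0:
        prof = metaprofile(
            mean_tracks["SD"].values, fragmap, pre_centers,
            half_width=config.metaprofile_half_width, bin_size=config.metaprofile_bin,
        )
        imax = int(np.nanargmax(prof.mean_signal))
        center = len(prof.offsets) // 2
        flank = np.nanmean(np.concatenate([prof.mean_signal[:5], prof.mean_signal[-5:]]))
        meta_block = {
            "n_centers": prof.n_intervals,
            "max_offset_bp": int(prof.offsets[imax]),
            "center_signal": float(prof.mean_signal[center]),
            "flank_signal": float(flank),
        }
        if out is not None:
            pd.DataFrame({"offset": prof.offsets, "mean_signal": prof.mean_signal}).to_csv(
                out / "metaprofile_SD_at_PREs.tsv", sep="\t", index=False
            )

    # ---- stage: expression post-statistics
    expr_block = {}
    for name, de in de_tables.items():
        detected = de[de["base_mean"] > 0]
        skew = l2fc_skewness(detected["l2fc"])
        deg = de[de["q"] < config.alpha_q]
        eq = equivalence_test(de, fold_bound=config.fold_bound, alpha_q=config.alpha_q)
        expr_block[name] = {
            "n_genes": int(len(de)),
            "skewness": skew.skewness,
            "n_deg": int(len(deg)),
            "frac_deg_negative": float((deg["l2fc"] < 0).mean()) if len(deg) else float("nan"),
            "frac_unchanged": float(eq["unchanged"].mean()),
        }
    # unchanged fraction, in the mutant contrast, of genes repressed in the wild type
    wt = de_tables["SD_vs_CD"]
    repressed = set(wt.loc[(wt["q"] < config.alpha_q) & (wt["l2fc"] < 0), "gene_id"])
    mut = de_tables["SD_vs_CD_mutant"]
    mut_sub = mut[mut["gene_id"].isin(repressed)]
    if len(mut_sub):
        eq_mut = equivalence_test(mut_sub, fold_bound=config.fold_bound, alpha_q=config.alpha_q)
        expr_block["repressed_in_wt_unchanged_in_mutant"] = float(eq_mut["unchanged"].mean())

    # ---- stage: per-gene occupancy differences
    occ = compare_occupancy(
        mean_tracks["CD"], mean_tracks["SD"], genome,
        min_abs_delta=config.min_abs_delta, upstream=config.upstream,
    )
    occ_block = {
        "n_group1": int((occ["group"] == "1").sum()),
        "n_group2": int((occ["group"] == "2").sum()),
        "n_unchanged": int((occ["group"] == "unchanged").sum()),
    }

    # ---- stage: regulon inference
    windows = promoter_windows(genome, sim_cfg.promoter_width)
    de_for_regulons = de_tables["SD_vs_CD"]
    regulons: list[Regulon] = []
    regulon_block: dict[str, dict] = {}
    tau_errors = []
    jaccards = []
    for motif in truth.motifs:
        hits = scan_motif(genome, motif, keep_top_frac=config.keep_top_frac)
        curve = threshold_curve(
            hits, windows, de_for_regulons, config.tau_grid(), n_min=config.n_min_regulon
        )
        tau = config.tau_overrides.get(motif.tf_name, curve.tau_star)
        reg = build_regulon(hits, windows, tau, tf_name=motif.tf_name)
        reg.curve = curve
        regulons.append(reg)
        truth_set = truth.true_regulons.get(motif.tf_name, set())
        union = reg.genes | truth_set
        jac = len(reg.genes & truth_set) / len(union) if union else float("nan")
        jaccards.append(jac)
        tau_true = truth.tf_thresholds.get(motif.tf_name, float("nan"))
        tau_err = abs(tau - tau_true)
        tau_errors.append(tau_err)
        regulon_block[motif.tf_name] = {
            "tau_star": float(tau), "tau_true": float(tau_true),
            "tau_abs_error": float(tau_err), "n_members": len(reg.genes),
            "jaccard_vs_truth": float(jac),
        }
        if out is not None:
            (out / "regulons").mkdir(exist_ok=True)
            curve.to_frame().to_csv(out / "regulons" / f"curve_{motif.tf_name}.tsv",
                                    sep="\t", index=False)
            pd.Series(sorted(reg.genes)).to_csv(
                out / "regulons" / f"regulon_{motif.tf_name}.tsv", index=False, header=False
            )
    universe = {g.gene_id for g in genome.genes}
    overlap_results = []
    if len(regulons) >= 2:
        from .motifs import regulon_overlap_tests

        overlap_results = regulon_overlap_tests(regulons, universe)
    regulon_block["overlaps"] = {
        f"{r.tf_a}|{r.tf_b}": {"odds_ratio": r.odds_ratio, "p": r.p, "q": r.q}
        for r in overlap_results
    }
    changed = set(wt.loc[wt["q"] < config.alpha_q, "gene_id"])
    union_members = set().union(*(r.genes for r in regulons)) if regulons else set()
    regulon_block["union_coverage_of_changed"] = (
        len(union_members & changed) / len(changed) if changed else float("nan")
    )

    # ---- recovery metrics
    recovery = {
        "peak_jaccard": {
            cond: bp_jaccard(called[cond].intervals(), truth.planted_peaks[cond])
            for cond in CONDITIONS
        },
        "regulon_jaccard_mean": float(np.mean(jaccards)) if jaccards else float("nan"),
        "tau_abs_error_mean": float(np.mean(tau_errors)) if tau_errors else float("nan"),
    }

    report = RunReport(
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        config=config.to_dict(),
        peaks={
            "n_peaks": {c: len(called[c]) for c in CONDITIONS},
            "n_planted": {c: len(truth.planted_peaks[c]) for c in CONDITIONS},
            "shared_fraction": shared_fraction,
        },
        recovery=recovery,
        enrichment=enrichment_block,
        chromatin_states=state_block,
        metaprofile=meta_block,
        expression=expr_block,
        occupancy_groups=occ_block,
        regulons=regulon_block,
    )
    if out is not None:
        write_report(report, out / "report.json")
    return report


def write_report(report: RunReport, path: str | Path) -> None:
    """Serialise a validated report as JSON with stable key order."""
    payload = report.model_dump()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)


def read_report(path: str | Path) -> RunReport:
    with open(path) as fh:
        return RunReport(**json.load(fh))
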
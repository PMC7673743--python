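"""Post-statistics on differential-expression tables.

These operate on consumed DE results (gene, base mean, l2fc, SE, p): the
skewness of the l2fc distribution as a repression signature, the practical
equivalence ("significantly unchanged") test against a fold-change bound,
IP/input enrichment, BH FDR, and equal-population binning.

The equivalence test treats the composite null |theta| >= Delta with
Delta = log2(fold_bound) via two one-sided normal tests (TOST): the
reported p is the larger of the two one-sided p-values, so rejection at
level alpha certifies that the true change is inside the equivalence
region with both one-sided tests significant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests


@dataclass
class SkewnessReport:
    n: int
    m2: float
    m3: float
    skewness: float


def l2fc_skewness(values) -> SkewnessReport:
    """Moment skewness m3 / m2^(3/2) with denominator-n central moments.

    No bias correction is applied; the statistic is meant to be computed
    over all detected genes, not only significant ones.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values for skewness")
    mu = x.mean()
    m2 = float(((x - mu) ** 2).mean())
    m3 = float(((x - mu) ** 3).mean())
    if m2 == 0:
        raise ValueError("skewness undefined for constant input (m2 = 0)")
    return SkewnessReport(n=n, m2=m2, m3=m3, skewness=m3 / m2**1.5)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def equivalence_test(
    table: pd.DataFrame, fold_bound: float = 1.5, alpha_q: float = 0.1
) -> pd.DataFrame:
    """Flag genes whose expression is practically unchanged.

    The region of practical equivalence is a change of no more than
    ``fold_bound`` in either direction; the null of at least that change is
    tested per gene using the gene-wise SE of the l2fc and a normality
    assumption.  Returns the table with p_equiv, q_equiv and the unchanged
    flag (q_equiv < alpha_q) appended.
    """
    if fold_bound <= 1:
        raise ValueError("fold_bound must exceed 1")
    se = table["se"].to_numpy(dtype=float)
    if np.any(~(se > 0)):
        bad = table.loc[~(se > 0), "gene_id"].tolist()
        raise ValueError(f"nonpositive SE for genes: {bad[:10]}")
    delta = np.log2(fold_bound)
    l2fc = table["l2fc"].to_numpy(dtype=float)
    p_lo = norm.cdf((l2fc - delta) / se)   # H0: theta >= +Delta
    p_hi = norm.cdf((-l2fc - delta) / se)  # H0: theta <= -Delta
    p_equiv = np.maximum(p_lo, p_hi)
    out = table.copy()
    out["p_equiv"] = p_equiv
    out["q_equiv"] = bh_fdr(p_equiv)
    out["unchanged"] = out["q_equiv"] < alpha_q
    out.attrs["rope_l2fc"] = float(delta)
    return out


def ip_input_enrichment(
    ip_counts: pd.Series, input_counts: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene log2(IP/input) on depth-normalised counts.

    Positive values flag genes enriched in the cell-type-specific IP
    fraction relative to whole-tissue input.
    """
    if set(ip_counts.index) != set(input_counts.index):
        raise ValueError("IP and input gene universes differ")
    input_counts = input_counts.reindex(ip_counts.index)
    for name, s in (("IP", ip_counts), ("input", input_counts)):
        if s.sum() <= 0:
            raise ValueError(f"{name} library size must be positive")
    cpm_ip = ip_counts * 1e6 / ip_counts.sum()
    cpm_in = input_counts * 1e6 / input_counts.sum()
    enr = np.log2((cpm_ip + pseudocount) / (cpm_in + pseudocount))
    flag = np.where(enr > 0, "enriched", np.where(enr < 0, "depleted", "neutral"))
    return pd.DataFrame(
        {"gene_id": ip_counts.index, "log2_enrichment": enr.to_numpy(), "flag": flag}
    ).reset_index(drop=True)


def bin_equally_populated(values, k: int = 7) -> np.ndarray:
    """Rank values into k bins whose sizes differ by at most one.

    Ties are broken by stable input order, matching the equal-population
    binning used to feed continuous scores into pathway analysis.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x = np.asarray(values)
    n = len(x)
    if n < k:
        raise ValueError("need at least k values")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * k) // n
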
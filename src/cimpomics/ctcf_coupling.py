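"""CTCF-methylation coupling: site classification, correlation, CpG positions.

CTCF sites are classified lost / unchanged / gained from differential
binding (FDR < 0.05 and |log2FC| > 1 by default). Binding changes are
correlated with methylation changes at overlapping regions, and CpG
dinucleotide frequency is profiled per motif position (1-based position of
the CpG's C, motif-forward orientation) with a one-sided Fisher enrichment
between site classes.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import GenomicInterval, build_tree, overlap_length, tree_overlaps
from .stats import bh_adjust


def classify_ctcf_sites(
    diff_ctcf: pd.DataFrame, fdr: float = 0.05, lfc: float = 1.0
) -> pd.Series:
    """Per-site class: lost (down, significant), gained (up, significant), else unchanged."""
    f = diff_ctcf["FDR"].to_numpy(dtype=float)
    l = diff_ctcf["log2FC"].to_numpy(dtype=float)
    cls = np.full(len(diff_ctcf), "unchanged", dtype=object)
    with np.errstate(invalid="ignore"):
        cls[(f < fdr) & (l < -lfc)] = "lost"
        cls[(f < fdr) & (l > lfc)] = "gained"
    return pd.Series(cls, index=diff_ctcf.index, name="class")


def coupling_correlation(
    diff_ctcf: pd.DataFrame,
    diff_meth: pd.DataFrame,
    ctcf_intervals: Sequence[GenomicInterval],
    meth_intervals: Sequence[GenomicInterval],
    n_bins: int = 25,
) -> dict:
    """Correlation between methylation change and CTCF binding change.

    Regions join by >= 1 bp overlap; each methylation region keeps the one
    CTCF peak with maximal overlap (ties broken by smallest binding FDR).
    Returns Pearson r, Spearman rho, their p-values, the joined pairs and a
    hexbin-style binned count table for plotting.
    """
    ctcf_by_id = {iv.id: iv for iv in ctcf_intervals}
    trees = build_tree(ctcf_intervals)

    pairs = []
    for meth_iv in meth_intervals:
        if meth_iv.id not in diff_meth.index:
            continue
        hits = tree_overlaps(trees, meth_iv)
        hits = [h for h in hits if h.id in diff_ctcf.index]
        if not hits:
            continue

        def rank(h):
            fdr = diff_ctcf.loc[h.id, "FDR"]
            return (-overlap_length(meth_iv, h), fdr if pd.notna(fdr) else 2.0, h.id)

        best = min(hits, key=rank)
        m_lfc = diff_meth.loc[meth_iv.id, "log2FC"]
        c_lfc = diff_ctcf.loc[best.id, "log2FC"]
        if pd.isna(m_lfc) or pd.isna(c_lfc):
            continue
        pairs.append({"meth_id": meth_iv.id, "ctcf_id": best.id,
                      "meth_log2FC": float(m_lfc), "ctcf_log2FC": float(c_lfc)})
    joined = pd.DataFrame(pairs)
    if len(joined) < 3:
        return {"n": len(joined), "pearson_r": np.nan, "pearson_p": np.nan,
                "spearman_rho": np.nan, "spearman_p": np.nan,
                "pairs": joined, "binned": None}
    r, rp = sps.pearsonr(joined["meth_log2FC"], joined["ctcf_log2FC"])
    rho, sp = sps.spearmanr(joined["meth_log2FC"], joined["ctcf_log2FC"])
    binned, xe, ye = np.histogram2d(
        joined["meth_log2FC"], joined["ctcf_log2FC"], bins=n_bins
    )
    return {
        "n": int(len(joined)),
        "pearson_r": float(r), "pearson_p": float(rp),
        "spearman_rho": float(rho), "spearman_p": float(sp),
        "pairs": joined,
        "binned": pd.DataFrame(binned, index=xe[:-1], columns=ye[:-1]),
    }


def methylation_by_binding_class(
    classes: pd.Series, meth_log2fc: pd.Series
) -> pd.DataFrame:
    """Methylation change per binding class with pairwise rank-sum p-values.

    Pairwise comparisons are reported without multiplicity adjustment.
    """
    aligned = pd.DataFrame({"class": classes, "meth_log2FC": meth_log2fc}).dropna()
    rows = []
    labels = ["lost", "unchanged", "gained"]
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa = aligned.loc[aligned["class"] == a, "meth_log2FC"]
            xb = aligned.loc[aligned["class"] == b, "meth_log2FC"]
            if len(xa) and len(xb):
                _, p = sps.ranksums(xa, xb)
            else:
                p = np.nan
            rows.append({"group_a": a, "group_b": b,
                         "median_a": float(xa.median()) if len(xa) else np.nan,
                         "median_b": float(xb.median()) if len(xb) else np.nan,
                         "ranksum_p": float(p) if p == p else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CpG positional analysis
# ---------------------------------------------------------------------------

def cpg_motif_profile(sequences: Iterable[str]) -> pd.Series:
    """Per-position CpG start frequency over motif-aligned sequences.

    frequency[p] (1-based) is the fraction of sites whose bases (p, p+1)
    are (C, G). Sequences must be equal length and motif-forward.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("empty site list")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be motif-aligned to equal length")
    L = lengths.pop()
    counts = np.zeros(L - 1)
    for s in seqs:
        for p in range(L - 1):
            if s[p] == "C" and s[p + 1] == "G":
                counts[p] += 1
    freq = counts / len(seqs)
    return pd.Series(freq, index=np.arange(1, L), name="cpg_frequency")


def positional_enrichment(
    group_a_sequences: Sequence[str],
    group_b_sequences: Sequence[str],
    positions_of_interest: frozenset[int] | set[int] = frozenset({5, 15}),
) -> pd.DataFrame:
    """Per-position CpG enrichment in group A vs group B (one-sided Fisher).

    Tests every motif position; BH adjusts across positions. The
    ``positions_of_interest`` column simply marks the canonical positions.
    """
    def cpg_presence(seqs, p):
        return sum(1 for s in seqs if s[p - 1: p + 1].upper() == "CG")

    a = list(group_a_sequences)
    b = list(group_b_sequences)
    if not a or not b:
        raise ValueError("both groups need at least one site")
    L = len(a[0])
    rows = []
    for p in range(1, L):
        ca = cpg_presence(a, p)
        cb = cpg_presence(b, p)
        table = [[ca, len(a) - ca], [cb, len(b) - cb]]
        odds, pval = sps.fisher_exact(table, alternative="greater")
        rows.append({"position": p, "cpg_a": ca, "cpg_b": cb,
                     "odds_ratio": odds, "pvalue": pval,
                     "of_interest": p in positions_of_interest})
    df = pd.DataFrame(rows).set_index("position")
    df["FDR"] = bh_adjust(df["pvalue"].to_numpy())
    return df
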
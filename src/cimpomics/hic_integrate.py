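"""Hi-C TAD/loop integration with CTCF binding and gene expression.

TAD boundaries are 5 kb regions centered on each border and keep at most one
overlapping CTCF peak (smallest FDR, ties by genomic start). Loop anchors
get 5 kb padding on each side; enhancer-promoter (EP) loops need an
enhancer within 25 kb of one padded anchor and a promoter within 25 kb of
the other. Differential 3D scores delegate to the NB Wald test for integer
scores or a Welch test on log2 scores otherwise.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import GenomicInterval, build_tree, tree_overlaps
from .quantify import CountMatrix
from .stats import DIFF_COLUMNS, bh_adjust, nb_wald

BOUNDARY_WIDTH = 5000
ANCHOR_PAD = 5000
EP_MAX_DIST = 25000


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Interval gap in bp; 0 when overlapping, large when on different chromosomes."""
    if a.chrom != b.chrom:
        return 10 ** 12
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def tad_boundaries(tad: GenomicInterval, width: int = BOUNDARY_WIDTH) -> tuple[
    GenomicInterval, GenomicInterval
]:
    half = width // 2
    left = GenomicInterval(tad.chrom, max(0, tad.start - half), tad.start + half)
    right = GenomicInterval(tad.chrom, max(0, tad.end - half), tad.end + half)
    return left, right


def annotate_boundaries(
    tads: Sequence[GenomicInterval],
    diff_ctcf: pd.DataFrame,
    ctcf_intervals: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Per-TAD boundary annotation with the minimum-FDR overlapping CTCF peak.

    Ties in FDR resolve to the smaller genomic start; boundaries without an
    overlapping peak are kept with a null peak id.
    """
    trees = build_tree([iv for iv in ctcf_intervals if iv.id in diff_ctcf.index])
    rows = []
    for tad in tads:
        for side, boundary in zip(("left", "right"), tad_boundaries(tad)):
            hits = tree_overlaps(trees, boundary)
            best_id, best_fdr, best_lfc = None, np.nan, np.nan
            if hits:
                def rank(h):
                    fdr = diff_ctcf.loc[h.id, "FDR"]
                    return (fdr if pd.notna(fdr) else 2.0, h.start, h.id)

                best = min(hits, key=rank)
                best_id = best.id
                best_fdr = diff_ctcf.loc[best.id, "FDR"]
                best_lfc = diff_ctcf.loc[best.id, "log2FC"]
            rows.append({
                "tad_id": tad.id, "side": side,
                "boundary_chrom": boundary.chrom,
                "boundary_start": boundary.start, "boundary_end": boundary.end,
                "ctcf_peak": best_id, "ctcf_FDR": best_fdr, "ctcf_log2FC": best_lfc,
            })
    return pd.DataFrame(rows)


def pad_anchor(chrom: str, start: int, end: int, pad: int = ANCHOR_PAD) -> GenomicInterval:
    return GenomicInterval(chrom, max(0, start - pad), end + pad)


def call_ep_loops(
    loops: pd.DataFrame,
    enhancers: Sequence[GenomicInterval],
    promoters: Sequence[GenomicInterval],
    max_dist: int = EP_MAX_DIST,
    pad: int = ANCHOR_PAD,
) -> pd.DataFrame:
    """Flag enhancer-promoter loops.

    ``loops`` is BEDPE-like with a name column; distances are measured from
    the padded anchor (0 when overlapping), inclusive at ``max_dist``. EP
    requires the enhancer and the promoter on opposite anchors; the gene id
    comes from the nearest qualifying promoter.
    """
    out = loops.copy()
    ep_flags, enh_ids, gene_ids = [], [], []
    for r in loops.itertuples():
        a1 = pad_anchor(r.chrom1, int(r.start1), int(r.end1), pad)
        a2 = pad_anchor(r.chrom2, int(r.start2), int(r.end2), pad)
        best = None
        for ea, pa in ((a1, a2), (a2, a1)):
            enh_near = [(e, _gap(ea, e)) for e in enhancers if _gap(ea, e) <= max_dist]
            prom_near = [(p, _gap(pa, p)) for p in promoters if _gap(pa, p) <= max_dist]
            if enh_near and prom_near:
                e, ed = min(enh_near, key=lambda x: (x[1], x[0].id or ""))
                p, pdist = min(prom_near, key=lambda x: (x[1], x[0].id or ""))
                cand = (ed + pdist, e.id, p.id)
                if best is None or cand < best:
                    best = cand
        if best is None:
            ep_flags.append(False)
            enh_ids.append(None)
            gene_ids.append(None)
        else:
            ep_flags.append(True)
            enh_ids.append(best[1])
            gene_ids.append(best[2])
    out["is_ep"] = ep_flags
    out["enhancer_id"] = enh_ids
    out["gene_id"] = gene_ids
    return out


def differential_3d(
    score_table: pd.DataFrame,
    groups: Mapping[str, str],
    contrast: tuple[str, str],
) -> pd.DataFrame:
    """Differential TAD inclusion-ratio or loop density scores.

    Integer scores run through the NB Wald test; non-integer scores use a
    Welch test on log2(score + 1) (mode recorded in ``attrs['mode']``).
    """
    values = score_table.to_numpy()
    if np.allclose(values, np.round(values)):
        cm = CountMatrix(score_table.round().astype(int), dict(groups))
        res = nb_wald(cm, contrast)
        res.attrs["mode"] = "nb-wald"
        return res
    g1, g2 = contrast
    c1 = [s for s in score_table.columns if groups.get(s) == g1]
    c2 = [s for s in score_table.columns if groups.get(s) == g2]
    logs = np.log2(score_table + 1.0)
    x1 = logs[c1].to_numpy()
    x2 = logs[c2].to_numpy()
    lfc = x2.mean(axis=1) - x1.mean(axis=1)
    t, p = sps.ttest_ind(x2, x1, axis=1, equal_var=False)
    se = np.where(t != 0, np.abs(lfc / np.where(t == 0, 1, t)), np.nan)
    res = pd.DataFrame({
        "baseMean": score_table.mean(axis=1),
        "log2FC": lfc, "SE": se, "stat": t, "pvalue": p,
        "FDR": bh_adjust(p), "status": "ok",
    }, index=score_table.index)[DIFF_COLUMNS]
    res.attrs["mode"] = "welch-log"
    return res


def ctcf_loop_linkage(
    diff_loops: pd.DataFrame,
    loops: pd.DataFrame,
    diff_ctcf: pd.DataFrame,
    ctcf_intervals: Sequence[GenomicInterval],
    fdr_cut: float = 0.05,
    pad: int = ANCHOR_PAD,
) -> dict:
    """Fractions of lost/gained loops with decreased anchor CTCF binding.

    A loop is lost (gained) at FDR < ``fdr_cut`` with negative (positive)
    log2FC. CTCF decrease defaults to sign-only (any overlapping anchor
    peak with log2FC < 0); a significance-gated variant is also reported,
    along with the mean anchor CTCF change per loop and a rank-sum test of
    lost vs gained loops.
    """
    trees = build_tree([iv for iv in ctcf_intervals if iv.id in diff_ctcf.index])

    rows = []
    for r in loops.itertuples():
        loop_id = r.name
        if loop_id not in diff_loops.index:
            continue
        lfc = diff_loops.loc[loop_id, "log2FC"]
        fdr = diff_loops.loc[loop_id, "FDR"]
        if pd.isna(lfc) or pd.isna(fdr):
            continue
        if fdr < fdr_cut and lfc < 0:
            status = "lost"
        elif fdr < fdr_cut and lfc > 0:
            status = "gained"
        else:
            status = "unchanged"
        a1 = pad_anchor(r.chrom1, int(r.start1), int(r.end1), pad)
        a2 = pad_anchor(r.chrom2, int(r.start2), int(r.end2), pad)
        hits = {h.id for h in tree_overlaps(trees, a1)} | {
            h.id for h in tree_overlaps(trees, a2)
        }
        lfcs = diff_ctcf.loc[sorted(hits), "log2FC"].dropna() if hits else pd.Series(dtype=float)
        fdrs = diff_ctcf.loc[lfcs.index, "FDR"] if len(lfcs) else pd.Series(dtype=float)
        rows.append({
            "loop_id": loop_id, "status": status,
            "n_anchor_peaks": int(len(lfcs)),
            "any_ctcf_decrease": bool((lfcs < 0).any()),
            "any_ctcf_decrease_significant": bool(
                ((lfcs < 0) & (fdrs < fdr_cut)).any()
            ),
            "mean_ctcf_log2FC": float(lfcs.mean()) if len(lfcs) else np.nan,
        })
    per_loop = pd.DataFrame(rows)

    def frac(status, col):
        sub = per_loop[(per_loop["status"] == status) & (per_loop["n_anchor_peaks"] > 0)]
        return float(sub[col].mean()) if len(sub) else np.nan

    lost = per_loop[per_loop["status"] == "lost"]["mean_ctcf_log2FC"].dropna()
    gained = per_loop[per_loop["status"] == "gained"]["mean_ctcf_log2FC"].dropna()
    if len(lost) and len(gained):
        _, ranksum_p = sps.ranksums(lost, gained)
    else:
        ranksum_p = np.nan
    return {
        "per_loop": per_loop,
        "n_lost": int((per_loop["status"] == "lost").sum()),
        "n_gained": int((per_loop["status"] == "gained").sum()),
        "lost_frac_ctcf_decrease": frac("lost", "any_ctcf_decrease"),
        "gained_frac_ctcf_decrease": frac("gained", "any_ctcf_decrease"),
        "lost_frac_ctcf_decrease_significant": frac(
            "lost", "any_ctcf_decrease_significant"),
        "gained_frac_ctcf_decrease_significant": frac(
            "gained", "any_ctcf_decrease_significant"),
        "mean_ctcf_log2FC_lost": float(lost.mean()) if len(lost) else np.nan,
        "mean_ctcf_log2FC_gained": float(gained.mean()) if len(gained) else np.nan,
        "ranksum_p": float(ranksum_p) if ranksum_p == ranksum_p else np.nan,
    }


def loop_expression_correlation(
    diff_ep_loops: pd.DataFrame,
    diff_expr: pd.DataFrame,
) -> dict:
    """Spearman correlation of EP-loop strength change with contacted-gene expression change.

    ``diff_ep_loops`` must carry log2FC and gene_id columns (EP loops only).
    """
    pairs = []
    for loop_id, row in diff_ep_loops.iterrows():
        gid = row.get("gene_id")
        if gid is None or gid not in diff_expr.index:
            continue
        if pd.isna(row["log2FC"]) or pd.isna(diff_expr.loc[gid, "log2FC"]):
            continue
        pairs.append((loop_id, gid, float(row["log2FC"]),
                      float(diff_expr.loc[gid, "log2FC"])))
    df = pd.DataFrame(pairs, columns=["loop_id", "gene_id", "loop_log2FC",
                                      "expr_log2FC"])
    if len(df) < 3:
        return {"n": len(df), "spearman_rho": np.nan, "spearman_p": np.nan, "pairs": df}
    rho, p = sps.spearmanr(df["loop_log2FC"], df["expr_log2FC"])
    return {"n": int(len(df)), "spearman_rho": float(rho), "spearman_p": float(p),
            "pairs": df}


def summarize_ctcf_3d_overlap(
    ctcf_peaks: Sequence[GenomicInterval],
    boundaries: Sequence[GenomicInterval],
    padded_anchors: Sequence[GenomicInterval],
    variable_ids: set[str] | None = None,
) -> dict:
    """Fractions of CTCF peaks overlapping TAD boundaries / loop anchors.

    Optionally stratified by variable vs unchanged peaks; stratum fractions
    recombine to the overall fraction by peak-count weighting.
    """
    b_trees = build_tree(boundaries)
    a_trees = build_tree(padded_anchors)
    rows = []
    for pk in ctcf_peaks:
        rows.append({
            "id": pk.id,
            "in_boundary": bool(tree_overlaps(b_trees, pk)),
            "in_anchor": bool(tree_overlaps(a_trees, pk)),
            "variable": bool(variable_ids and pk.id in variable_ids),
        })
    df = pd.DataFrame(rows)
    out = {
        "n_peaks": int(len(df)),
        "frac_boundary": float(df["in_boundary"].mean()),
        "frac_anchor": float(df["in_anchor"].mean()),
    }
    if variable_ids is not None:
        for label, sub in df.groupby("variable"):
            key = "variable" if label else "unchanged"
            out[f"frac_boundary_{key}"] = float(sub["in_boundary"].mean())
            out[f"frac_anchor_{key}"] = float(sub["in_anchor"].mean())
            out[f"n_{key}"] = int(len(sub))
    return out
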
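"""Joining differential epigenetic signal to differential expression.

Starburst integration pairs per-gene promoter methylation changes with
expression changes; the axes of the starburst are signed -log10(FDR) scores.
Enhancer-accessibility integration first assigns enhancers to target genes
by an ensemble of evidence layers (distance, accessibility correlation,
shared TAD, loop contact, database), then joins accessibility to expression
per (enhancer, gene) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import GenomicInterval, build_tree, tree_overlaps

FDR_FLOOR = 1e-320
EVIDENCE_PRECEDENCE = ("loop", "database", "correlation", "nearest")


def signed_score(lfc: np.ndarray, fdr: np.ndarray) -> np.ndarray:
    """-log10(FDR) with the sign of the fold change, capped against underflow."""
    fdr = np.maximum(np.asarray(fdr, dtype=float), FDR_FLOOR)
    return -np.log10(fdr) * np.sign(np.asarray(lfc, dtype=float))


def _classify(meth_lfc, meth_fdr, expr_lfc, expr_fdr, fdr_cut, lfc_cut):
    sig_m = (meth_fdr < fdr_cut) & (np.abs(meth_lfc) > lfc_cut)
    sig_e = (expr_fdr < fdr_cut) & (np.abs(expr_lfc) > lfc_cut)
    out = np.full(len(meth_lfc), "not-significant", dtype=object)
    both = sig_m & sig_e
    out[both & (meth_lfc > 0) & (expr_lfc < 0)] = "hypermethylated-silenced"
    out[both & (meth_lfc < 0) & (expr_lfc > 0)] = "hypomethylated-activated"
    out[both & (np.sign(meth_lfc) == np.sign(expr_lfc))] = "discordant"
    return out


def starburst_join(
    diff_meth_promoters: pd.DataFrame,
    diff_expr: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 2.0,
    gene_annotation: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Join per-gene differential methylation with differential expression.

    Both tables must be indexed by gene id with columns log2FC and FDR. A
    gene is colored when both layers pass FDR < ``fdr_cut`` and |log2FC| >
    ``lfc_cut``; hypermethylated-silenced means methylation up and
    expression down. The correlation summary reports Pearson r both on
    signed -log10(FDR) scores and on raw log2 fold changes.
    """
    shared = diff_meth_promoters.index.intersection(diff_expr.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between methylation and expression tables")
    m = diff_meth_promoters.loc[shared]
    e = diff_expr.loc[shared]
    ok = m["log2FC"].notna() & m["FDR"].notna() & e["log2FC"].notna() & e["FDR"].notna()
    m, e = m.loc[ok], e.loc[ok]

    meth_score = signed_score(m["log2FC"].to_numpy(), m["FDR"].to_numpy())
    expr_score = signed_score(e["log2FC"].to_numpy(), e["FDR"].to_numpy())
    classes = _classify(
        m["log2FC"].to_numpy(), m["FDR"].to_numpy(),
        e["log2FC"].to_numpy(), e["FDR"].to_numpy(), fdr_cut, lfc_cut,
    )
    records = pd.DataFrame(
        {
            "meth_log2FC": m["log2FC"], "meth_FDR": m["FDR"],
            "expr_log2FC": e["log2FC"], "expr_FDR": e["FDR"],
            "meth_score": meth_score, "expr_score": expr_score,
            "class": classes,
        },
        index=m.index,
    )
    if gene_annotation is not None:
        records["is_tf"] = gene_annotation.reindex(records.index)["is_tf"].fillna(False)
        records["is_hematopoietic"] = (
            gene_annotation.reindex(records.index)["is_hematopoietic"].fillna(False)
        )

    r_s, p_s = sps.pearsonr(meth_score, expr_score) if len(records) > 2 else (np.nan, np.nan)
    r_l, p_l = (
        sps.pearsonr(m["log2FC"], e["log2FC"]) if len(records) > 2 else (np.nan, np.nan)
    )
    summary = {
        "n_genes": int(len(records)),
        "pearson_r_signed_score": float(r_s), "pearson_p_signed_score": float(p_s),
        "pearson_r_log2fc": float(r_l), "pearson_p_log2fc": float(p_l),
        "n_hypermethylated_silenced": int((classes == "hypermethylated-silenced").sum()),
        "n_hypomethylated_activated": int((classes == "hypomethylated-activated").sum()),
    }
    return records, summary


# ---------------------------------------------------------------------------
# ensemble enhancer-gene assignment
# ---------------------------------------------------------------------------

@dataclass
class EnhancerAssignment:
    enhancer_id: str
    gene_id: str
    evidence: tuple[str, ...]
    tier: int
    distance: int
    flagged_no_tad: bool = False


def _interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 10 ** 12
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if b.start >= a.end else a.start - b.end


def assign_enhancers(
    enhancers: Sequence[GenomicInterval],
    genes: Sequence[tuple[str, str, int, str]],
    tads: Sequence[GenomicInterval],
    loops: pd.DataFrame,
    enhancer_counts: pd.DataFrame | None = None,
    promoter_counts: pd.DataFrame | None = None,
    db_map: Mapping[str, str] | None = None,
    max_distance: int = 1_000_000,
    corr_min: float = 0.3,
    min_corr_samples: int = 8,
    anchor_pad: int = 5000,
) -> pd.DataFrame:
    """Assign each enhancer to a target gene by ensemble evidence.

    Candidate genes lie within ``max_distance`` of the enhancer and in the
    same TAD (an enhancer outside all TADs falls back to distance only and
    is flagged). Evidence flags: nearest candidate gene; enhancer-promoter
    accessibility correlation >= ``corr_min`` over >= ``min_corr_samples``
    samples; a loop whose padded anchors contact both elements; a database
    assignment. The winner has the highest flag count, ties broken by
    loop > database > correlation > nearest, then smallest distance.
    """
    db_map = db_map or {}
    tad_trees = build_tree(tads)

    gene_points = {
        gid: GenomicInterval(chrom, max(0, tss - 1), tss + 1, strand, gid)
        for gid, chrom, tss, strand in genes
    }

    loop_pairs = []
    if loops is not None and len(loops):
        for r in loops.itertuples():
            a1 = GenomicInterval(r.chrom1, max(0, int(r.start1) - anchor_pad),
                                 int(r.end1) + anchor_pad)
            a2 = GenomicInterval(r.chrom2, max(0, int(r.start2) - anchor_pad),
                                 int(r.end2) + anchor_pad)
            loop_pairs.append((a1, a2))

    rows = []
    for enh in enhancers:
        enh_tads = tree_overlaps(tad_trees, enh)
        flagged_no_tad = len(enh_tads) == 0
        candidates = []
        for gid, gp in gene_points.items():
            d = _interval_gap(enh, gp)
            if d > max_distance:
                continue
            if not flagged_no_tad:
                gene_tads = tree_overlaps(tad_trees, gp)
                if not set(t.id for t in enh_tads) & set(t.id for t in gene_tads):
                    continue
            candidates.append((gid, d))
        if not candidates:
            continue
        nearest_gid = min(candidates, key=lambda x: (x[1], x[0]))[0]

        scored = []
        for gid, d in candidates:
            evidence = []
            for a1, a2 in loop_pairs:
                gp = gene_points[gid]
                if (a1.overlaps(enh) and a2.overlaps(gp)) or (
                    a2.overlaps(enh) and a1.overlaps(gp)
                ):
                    evidence.append("loop")
                    break
            if db_map.get(enh.id) == gid:
                evidence.append("database")
            if (
                enhancer_counts is not None
                and promoter_counts is not None
                and enh.id in enhancer_counts.index
                and gid in promoter_counts.index
            ):
                shared_samples = enhancer_counts.columns.intersection(
                    promoter_counts.columns
                )
                if len(shared_samples) >= min_corr_samples:
                    x = enhancer_counts.loc[enh.id, shared_samples].to_numpy(float)
                    y = promoter_counts.loc[gid, shared_samples].to_numpy(float)
                    if x.std() > 0 and y.std() > 0:
                        r, _ = sps.pearsonr(np.log1p(x), np.log1p(y))
                        if r >= corr_min:
                            evidence.append("correlation")
            if gid == nearest_gid:
                evidence.append("nearest")
            if not flagged_no_tad:
                pass  # same-TAD holds for every candidate by construction
            scored.append((gid, d, tuple(evidence)))

        def sort_key(item):
            gid, d, ev = item
            prec = tuple(-(1 if flag in ev else 0) for flag in EVIDENCE_PRECEDENCE)
            return (-len(ev), prec, d, gid)

        scored.sort(key=sort_key)
        gid, d, ev = scored[0]
        if not ev:
            ev = ("nearest",) if gid == nearest_gid else ev
        rows.append(
            {
                "enhancer_id": enh.id, "gene_id": gid,
                "evidence": ",".join(ev), "tier": len(ev),
                "distance": d, "flagged_no_tad": flagged_no_tad,
            }
        )
    return pd.DataFrame(rows).set_index("enhancer_id") if rows else pd.DataFrame(
        columns=["gene_id", "evidence", "tier", "distance", "flagged_no_tad"]
    )


def enhancer_expression_join(
    diff_atac_enhancers: pd.DataFrame,
    enhancer_map: pd.DataFrame,
    diff_expr: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-(enhancer, gene) join of accessibility and expression changes.

    Unmapped enhancers are excluded (count reported); concordant classes
    require both layers significant with matching sign. Distance labels bin
    the enhancer-TSS distance in kb.
    """
    mapped = diff_atac_enhancers.index.intersection(enhancer_map.index)
    n_unmapped = len(diff_atac_enhancers.index) - len(mapped)
    rows = []
    for enh_id in mapped:
        gene_id = enhancer_map.loc[enh_id, "gene_id"]
        if gene_id not in diff_expr.index:
            continue
        a = diff_atac_enhancers.loc[enh_id]
        e = diff_expr.loc[gene_id]
        if pd.isna(a["log2FC"]) or pd.isna(e["log2FC"]):
            continue
        sig_a = a["FDR"] < fdr_cut and abs(a["log2FC"]) > lfc_cut
        sig_e = e["FDR"] < fdr_cut and abs(e["log2FC"]) > lfc_cut
        if sig_a and sig_e:
            if a["log2FC"] > 0 and e["log2FC"] > 0:
                cls = "concordant-activated"
            elif a["log2FC"] < 0 and e["log2FC"] < 0:
                cls = "concordant-silenced"
            else:
                cls = "discordant"
        else:
            cls = "not-significant"
        dist = int(enhancer_map.loc[enh_id, "distance"])
        rows.append(
            {
                "enhancer_id": enh_id, "gene_id": gene_id,
                "atac_log2FC": a["log2FC"], "atac_FDR": a["FDR"],
                "expr_log2FC": e["log2FC"], "expr_FDR": e["FDR"],
                "atac_score": float(signed_score(np.array([a["log2FC"]]),
                                                 np.array([a["FDR"]]))[0]),
                "expr_score": float(signed_score(np.array([e["log2FC"]]),
                                                 np.array([e["FDR"]]))[0]),
                "class": cls,
                "distance_label": f"{dist // 1000}kb",
            }
        )
    records = pd.DataFrame(rows)
    if len(records) > 2:
        r_s, p_s = sps.pearsonr(records["atac_score"], records["expr_score"])
        r_l, p_l = sps.pearsonr(records["atac_log2FC"], records["expr_log2FC"])
    else:
        r_s = p_s = r_l = p_l = float("nan")
    summary = {
        "n_pairs": int(len(records)), "n_unmapped_enhancers": int(n_unmapped),
        "pearson_r_signed_score": float(r_s), "pearson_p_signed_score": float(p_s),
        "pearson_r_log2fc": float(r_l), "pearson_p_log2fc": float(p_l),
    }
    return records, summary
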